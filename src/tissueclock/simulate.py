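"""Synthetic multi-tissue methylation panels with planted aging markers.

The generator emulates the structure of a multi-tissue beta-value study:
a shared probe universe, per-tissue cohorts with uniformly distributed
ages, a set of *common* markers whose methylation drifts linearly with
age in every tissue, per-tissue *specific* markers that drift in exactly
one tissue, and annotation (CpG island/shore relation, conservation
scores) whose distribution differs between the two marker classes. Two
platform dialects with overlapping probe sets can be exported per tissue.

Beta trajectories are linear on the beta scale with additive Gaussian
noise and clamping to [0, 1]; intercepts are sampled so that clamping is
rare at default settings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tissueclock.containers import (
    ANNOTATION_COLUMNS,
    GENE_STRUCTURES,
    BetaMatrix,
)
from tissueclock import io as mio

#: Beta-distribution concentration for conservation scores (a+b); larger
#: means tighter scores around the configured group mean.
CONSERVATION_CONCENTRATION = 20.0
#: Conservation mean for unplanted (null) probes.
BACKGROUND_CONSERVATION_MEAN = 0.45
#: Background gene-structure frequencies, shared by all probe classes.
GENE_STRUCTURE_PROBS = (0.20, 0.05, 0.10, 0.35, 0.05, 0.25)


class ConfigError(ValueError):
    """A simulation configuration field violates its constraints."""


@dataclass
class SimConfig:
    """Study-design knobs for one synthetic multi-tissue panel."""

    n_tissues: int = 3
    n_samples_per_tissue: int = 150
    n_probes: int = 2000
    n_common_markers: int = 20
    n_specific_markers_per_tissue: int = 15
    frac_positive_common: float = 0.8
    frac_positive_specific: float = 0.4
    age_range: tuple[float, float] = (20.0, 90.0)
    slope_magnitude: float = 0.005
    noise_sd: float = 0.02
    island_prob_common: float = 0.7
    island_prob_specific: float = 0.3
    island_prob_background: float = 0.4
    conservation_mean_common: float = 0.6
    conservation_mean_specific: float = 0.5
    missing_rate: float = 0.01
    platform_split: float = 0.5
    probe_overlap_frac: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        planted = self.n_common_markers + self.n_tissues * self.n_specific_markers_per_tissue
        if planted > self.n_probes:
            raise ConfigError(
                "n_common_markers + n_tissues * n_specific_markers_per_tissue "
                f"({planted}) exceeds n_probes ({self.n_probes})"
            )
        for name in (
            "n_tissues",
            "n_samples_per_tissue",
            "n_probes",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_common_markers", "n_specific_markers_per_tissue"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "frac_positive_common",
            "frac_positive_specific",
            "island_prob_common",
            "island_prob_specific",
            "island_prob_background",
            "conservation_mean_common",
            "conservation_mean_specific",
            "missing_rate",
            "platform_split",
            "probe_overlap_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError(f"age_range must satisfy min < max, got {self.age_range}")
        if self.slope_magnitude <= 0:
            raise ConfigError("slope_magnitude must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth for one panel.

    ``labels``: per-probe class (``common`` / ``specific`` / ``null``);
    ``specific_tissue``: owning tissue for specific markers, else None;
    ``directions``: +1 (methylation rises with age), -1, or 0 for null;
    ``slopes``: probes x tissues planted slopes in beta-units per year;
    ``platform_common_probes``: probe IDs present on both dialects.
    """

    probe_ids: pd.Index
    labels: pd.Series
    specific_tissue: pd.Series
    directions: pd.Series
    slopes: pd.DataFrame
    island_relation: pd.Series
    conservation: pd.Series
    platform_common_probes: pd.Index

    def markers(self, label: str | None = None) -> pd.Index:
        """Probe IDs of planted markers, optionally of one class."""
        if label is None:
            mask = self.labels != "null"
        else:
            mask = self.labels == label
        return self.probe_ids[mask.to_numpy()]

    def markers_for_tissue(self, tissue: str) -> pd.Index:
        """Markers with nonzero planted slope in the given tissue."""
        mask = self.slopes[tissue] != 0.0
        return self.probe_ids[mask.to_numpy()]


def _signed_directions(n: int, frac_positive: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-count direction assignment, order randomized."""
    n_pos = int(round(frac_positive * n))
    d = np.full(n, -1, dtype=int)
    d[:n_pos] = 1
    rng.shuffle(d)
    return d


def _island_relations(n: int, p_island: float, rng: np.random.Generator) -> np.ndarray:
    # remainder split evenly between shore and other
    p = [p_island, (1 - p_island) / 2.0, (1 - p_island) / 2.0]
    return rng.choice(["island", "shore", "other"], size=n, p=p)


def _conservation(n: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    nu = CONSERVATION_CONCENTRATION
    a = max(mean * nu, 1e-3)
    b = max((1.0 - mean) * nu, 1e-3)
    return rng.beta(a, b, size=n)


def generate_panel(
    config: SimConfig,
) -> tuple[list[BetaMatrix], list[pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Simulate one multi-tissue panel.

    Returns one :class:`BetaMatrix` and one sample table per tissue, the
    shared probe annotation, and the planted :class:`GroundTruth`. Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.n_probes
    T = config.n_tissues
    tissues = [f"tissue_{t + 1}" for t in range(T)]
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(P)], name="probe_id")

    # --- marker placement ------------------------------------------------
    planted_order = rng.permutation(P)
    n_common = config.n_common_markers
    n_spec = config.n_specific_markers_per_tissue
    common_idx = planted_order[:n_common]
    specific_idx = {
        t: planted_order[n_common + i * n_spec : n_common + (i + 1) * n_spec]
        for i, t in enumerate(tissues)
    }

    labels = np.full(P, "null", dtype=object)
    labels[common_idx] = "common"
    spec_tissue = np.full(P, None, dtype=object)
    for t in tissues:
        labels[specific_idx[t]] = "specific"
        spec_tissue[specific_idx[t]] = t

    directions = np.zeros(P, dtype=int)
    directions[common_idx] = _signed_directions(n_common, config.frac_positive_common, rng)
    for t in tissues:
        directions[specific_idx[t]] = _signed_directions(
            n_spec, config.frac_positive_specific, rng
        )

    slopes = np.zeros((P, T))
    for j, t in enumerate(tissues):
        active = np.concatenate([common_idx, specific_idx[t]]).astype(int)
        slopes[active, j] = directions[active] * config.slope_magnitude
    slopes_df = pd.DataFrame(slopes, index=probe_ids, columns=tissues)

    # --- annotation ------------------------------------------------------
    island = np.empty(P, dtype=object)
    cons = np.empty(P)
    for cls, p_isl, c_mean in (
        ("common", config.island_prob_common, config.conservation_mean_common),
        ("specific", config.island_prob_specific, config.conservation_mean_specific),
        ("null", config.island_prob_background, BACKGROUND_CONSERVATION_MEAN),
    ):
        mask = labels == cls
        k = int(mask.sum())
        island[mask] = _island_relations(k, p_isl, rng)
        cons[mask] = _conservation(k, c_mean, rng)

    gene_structure = rng.choice(GENE_STRUCTURES, size=P, p=GENE_STRUCTURE_PROBS)
    region_len = 500
    starts = np.arange(P, dtype=int) * 1000
    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids.to_numpy(),
            "gene_structure": gene_structure,
            "island_relation": island,
            "chrom": "chrS",
            "start": starts,
            "end": starts + region_len,
            "mean_conservation": cons,
        }
    )

    # --- platform-dialect probe subset -----------------------------------
    planted_mask = labels != "null"
    null_positions = np.flatnonzero(~planted_mask)
    n_overlap = int(round(config.probe_overlap_frac * P))
    n_null_keep = max(0, min(len(null_positions), n_overlap - int(planted_mask.sum())))
    kept_null = rng.choice(null_positions, size=n_null_keep, replace=False)
    common_probe_mask = planted_mask.copy()
    common_probe_mask[kept_null] = True
    platform_common = probe_ids[common_probe_mask]

    # --- per-tissue betas -------------------------------------------------
    lo, hi = config.age_range
    margin = max(0.05, 3.0 * config.noise_sd)
    matrices: list[BetaMatrix] = []
    sample_tables: list[pd.DataFrame] = []
    for j, t in enumerate(tissues):
        n = config.n_samples_per_tissue
        ages = rng.uniform(lo, hi, size=n)
        s = slopes[:, j]
        # intercepts keep b0 + s*age inside (margin, 1 - margin) over the range
        drift_lo = np.minimum(s * lo, s * hi)
        drift_hi = np.maximum(s * lo, s * hi)
        b0_lo = margin - drift_lo
        b0_hi = 1.0 - margin - drift_hi
        infeasible = b0_hi <= b0_lo
        if infeasible.any():
            raise ConfigError(
                "slope_magnitude x age_range leaves no room for intercepts "
                "inside (0, 1); reduce slope_magnitude or narrow age_range"
            )
        b0 = rng.uniform(b0_lo, b0_hi)
        clean = b0[:, None] + s[:, None] * ages[None, :]
        noisy = clean + rng.normal(0.0, config.noise_sd, size=(P, n))
        betas = np.clip(noisy, 0.0, 1.0)
        if config.missing_rate > 0:
            miss = rng.random((P, n)) < config.missing_rate
            betas = np.where(miss, np.nan, betas)
        sample_ids = [f"{t}_s{i:04d}" for i in range(n)]
        matrices.append(
            BetaMatrix(
                pd.DataFrame(betas, index=probe_ids, columns=sample_ids),
                platform="panel",
            )
        )
        sample_tables.append(
            pd.DataFrame({"sample_id": sample_ids, "age": ages, "tissue": t})
        )

    truth = GroundTruth(
        probe_ids=probe_ids,
        labels=pd.Series(labels, index=probe_ids, name="label"),
        specific_tissue=pd.Series(spec_tissue, index=probe_ids, name="specific_tissue"),
        directions=pd.Series(directions, index=probe_ids, name="direction"),
        slopes=slopes_df,
        island_relation=pd.Series(island, index=probe_ids, name="island_relation"),
        conservation=pd.Series(cons, index=probe_ids, name="mean_conservation"),
        platform_common_probes=platform_common,
    )
    return matrices, sample_tables, annotation, truth


def export_platform_dialects(
    mat: BetaMatrix,
    samples: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    out_dir: str | Path,
    tissue: str | None = None,
) -> tuple[Path, Path]:
    """Write one tissue's panel as two platform-dialect TSV files.

    Samples are partitioned by ``config.platform_split`` (that fraction,
    rounded, goes to the 27K-style export); the 27K dialect carries only
    the probes shared between dialects, the 450K dialect the full
    universe. Returns (path_27k, path_450k).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tissue = tissue or str(samples["tissue"].iloc[0])
    n = mat.shape[1]
    n_27k = int(round(config.platform_split * n))
    # deterministic partition: seed derived from panel seed and tissue
    rng = np.random.default_rng([config.seed, zlib.crc32(tissue.encode())])
    order = rng.permutation(n)
    cols = mat.sample_ids.to_numpy()
    cols_27k = sorted(cols[order[:n_27k]])
    cols_450k = sorted(cols[order[n_27k:]])

    mat_27k = BetaMatrix(
        mat.values.loc[truth.platform_common_probes, cols_27k], platform="27K"
    )
    mat_450k = BetaMatrix(mat.values.loc[:, cols_450k], platform="450K")
    p27 = out_dir / f"{tissue}_27K.tsv"
    p450 = out_dir / f"{tissue}_450K.tsv"
    mio.save_beta_matrix(mat_27k, p27)
    mio.save_beta_matrix(mat_450k, p450)
    return p27, p450
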