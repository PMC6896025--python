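"""End-to-end orchestration: simulate -> harmonize -> associate -> select
-> train -> evaluate -> characterize.

A :class:`RunConfig` carries every stage parameter with the reference
defaults (max_missing=10, FDR 0.05, 500 bootstraps, frequency > 0.95,
10-fold CV, 5 oldest/youngest) plus a master seed from which each
stochastic stage derives its own seed deterministically (CRC32 of the
stage name mixed with the master seed). A run writes per-stage outputs
and a manifest recording parameters, seeds, output checksums and row
counts, so identical configs reproduce identical runs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tissueclock import __version__
from tissueclock import io as mio
from tissueclock.association import select_age_probes
from tissueclock.characterize import (
    background_location_comparison,
    catalog_directions,
    classify_markers,
    conservation_compare,
    location_enrichment,
    positive_ratio_by_occurrence,
    young_old_contrast,
)
from tissueclock.clock import evaluate, grid_search_svr, predict_age, train_clock
from tissueclock.containers import BetaMatrix, ages_for
from tissueclock.simulate import SimConfig, export_platform_dialects, generate_panel
from tissueclock.stability import bootstrap_elastic_net, select_markers

STAGES = (
    "simulate",
    "harmonize",
    "associate",
    "select",
    "train",
    "evaluate",
    "characterize",
)
# each stage requires all of its predecessors in this linear DAG
_REQUIRES = {s: STAGES[:i] for i, s in enumerate(STAGES)}


class PipelineError(RuntimeError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "run"
    sim: SimConfig = field(default_factory=SimConfig)
    max_missing: int = 10
    normalize: bool | None = None
    fdr: float = 0.05
    n_boot: int = 500
    freq_threshold: float = 0.95
    cv_folds: int = 10
    k_young_old: int = 5
    test_fraction: float = 0.25
    master_seed: int = 0
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        enabled = set(self.stages)
        for s in self.stages:
            missing = [r for r in _REQUIRES[s] if r not in enabled]
            if missing:
                raise PipelineError(
                    f"stage {s!r} requires disabled stage(s) {missing}"
                )
        self.sim.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {s: stage_seed(config.master_seed, s) for s in STAGES},
        "stages": {},
    }
    state: dict = {}

    try:
        if "simulate" in enabled:
            _stage_simulate(config, out, manifest, state)
        if "harmonize" in enabled:
            _stage_harmonize(config, out, manifest, state)
        if "associate" in enabled:
            _stage_associate(config, out, manifest, state)
        if "select" in enabled:
            _stage_select(config, out, manifest, state)
        if "train" in enabled:
            _stage_train(config, out, manifest, state)
        if "evaluate" in enabled:
            _stage_evaluate(config, out, manifest, state)
        if "characterize" in enabled:
            _stage_characterize(config, out, manifest, state)
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"stage {state.get('current', '?')!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _record(manifest: dict, stage: str, outputs: dict[str, Path], **info) -> None:
    manifest["stages"][stage] = {
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
        **info,
    }


def _stage_simulate(config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    state["current"] = "simulate"
    sim = SimConfig.from_dict({**config.sim.to_dict(), "seed": stage_seed(config.master_seed, "simulate")})
    mats, tables, annotation, truth = generate_panel(sim)
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    outputs: dict[str, Path] = {}
    tissues = [str(t["tissue"].iloc[0]) for t in tables]
    for mat, tab, tissue in zip(mats, tables, tissues):
        p27, p450 = export_platform_dialects(mat, tab, truth, sim, data_dir, tissue)
        sp = data_dir / f"{tissue}_samples.tsv"
        mio.save_sample_table(tab, sp)
        outputs[f"{tissue}_27K"] = p27
        outputs[f"{tissue}_450K"] = p450
        outputs[f"{tissue}_samples"] = sp
    ap = data_dir / "annotation.tsv"
    mio.save_annotation(annotation, ap)
    outputs["annotation"] = ap
    state.update(tissues=tissues, annotation=annotation, truth=truth, data_dir=data_dir)
    _record(manifest, "simulate", outputs, n_probes=sim.n_probes, tissues=tissues)


def _stage_harmonize(config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    state["current"] = "harmonize"
    data_dir: Path = state["data_dir"]
    merged_mats: dict[str, BetaMatrix] = {}
    merged_tables: dict[str, pd.DataFrame] = {}
    outputs: dict[str, Path] = {}
    counts = {}
    for tissue in state["tissues"]:
        samples = mio.load_sample_table(data_dir / f"{tissue}_samples.tsv")
        dialects = []
        tables = []
        for dialect in ("27K", "450K"):
            mat = mio.load_beta_matrix(data_dir / f"{tissue}_{dialect}.tsv", dialect)
            if mat.shape[1] == 0:
                continue
            dialects.append(mat)
            tables.append(samples[samples["sample_id"].isin(mat.sample_ids)])
        merged, merged_tab = mio.harmonize(
            dialects, tables, max_missing=config.max_missing, normalize=config.normalize
        )
        # raw-beta variant (no quantile normalization) kept for the
        # direction/young-old analyses, which describe methylation levels
        raw, _ = mio.harmonize(dialects, tables, max_missing=config.max_missing,
                               normalize=False)
        merged_mats[tissue] = merged
        merged_tables[tissue] = merged_tab
        state.setdefault("merged_raw", {})[tissue] = raw
        mp = out / f"{tissue}_merged.tsv"
        mio.save_beta_matrix(merged, mp)
        outputs[f"{tissue}_merged"] = mp
        counts[tissue] = merged.shape[0]
    state.update(merged=merged_mats, merged_tables=merged_tables)
    _record(manifest, "harmonize", outputs, probes_after_filter=counts)


def _stage_associate(config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    state["current"] = "associate"
    outputs = {}
    selected = {}
    counts = {}
    for tissue, mat in state["merged"].items():
        res = select_age_probes(mat, state["merged_tables"][tissue], config.fdr)
        selected[tissue] = res
        ap = out / f"{tissue}_assoc.tsv"
        res.to_csv(ap, sep="\t", index_label="probe_id")
        outputs[f"{tissue}_assoc"] = ap
        counts[tissue] = len(res)
    state["assoc"] = selected
    _record(manifest, "associate", outputs, n_selected=counts)


def _stage_select(config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    state["current"] = "select"
    seed = stage_seed(config.master_seed, "select")
    outputs = {}
    markers = {}
    counts = {}
    for tissue, mat in state["merged"].items():
        probes = state["assoc"][tissue].index
        if len(probes) == 0:
            markers[tissue] = []
            counts[tissue] = 0
            continue
        sub = BetaMatrix(mat.values.loc[probes], platform=mat.platform)
        stab = bootstrap_elastic_net(
            sub,
            state["merged_tables"][tissue],
            n_boot=config.n_boot,
            freq_threshold=config.freq_threshold,
            seed=seed + zlib.crc32(tissue.encode()) % 10_000,
        )
        markers[tissue] = select_markers(stab)
        sp = out / f"{tissue}_markers.tsv"
        stab.to_csv(sp, sep="\t", index_label="probe_id")
        outputs[f"{tissue}_markers"] = sp
        counts[tissue] = len(markers[tissue])
    state["markers"] = markers
    _record(manifest, "select", outputs, n_markers=counts)


def _train_test_split(samples: pd.DataFrame, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    n = len(samples)
    n_test = int(round(test_fraction * n))
    order = rng.permutation(n)
    test_ids = set(samples["sample_id"].iloc[order[:n_test]])
    is_test = samples["sample_id"].isin(test_ids)
    return samples[~is_test], samples[is_test]


def _stage_train(config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    state["current"] = "train"
    seed = stage_seed(config.master_seed, "train")
    models = {}
    info = {}
    for tissue, mat in state["merged"].items():
        marker_ids = state["markers"][tissue]
        if not marker_ids:
            continue
        samples = state["merged_tables"][tissue]
        train_tab, test_tab = _train_test_split(samples, config.test_fraction, seed)
        train_mat = BetaMatrix(mat.values[train_tab["sample_id"]], platform=mat.platform)
        X = train_mat.values.loc[marker_ids].to_numpy().T
        y = ages_for(train_mat, train_tab)
        best, table = grid_search_svr(X, y, k=config.cv_folds, seed=seed)
        model = train_clock(train_mat, train_tab, marker_ids, best, tissue=tissue)
        model.cv_table = table
        models[tissue] = (model, train_tab, test_tab)
        info[tissue] = {"hyperparams": {k: v for k, v in best.items()},
                        "cv_mad": float(table["cv_mad"].min()),
                        "n_train": len(train_tab), "n_test": len(test_tab)}
    state["models"] = models
    _record(manifest, "train", {}, models=info)


def _stage_evaluate(config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    state["current"] = "evaluate"
    rows = []
    for tissue, (model, train_tab, test_tab) in state["models"].items():
        mat = state["merged"][tissue]
        test_mat = BetaMatrix(mat.values[test_tab["sample_id"]], platform=mat.platform)
        pred = predict_age(model, test_mat)
        met = evaluate(pred.to_numpy(), ages_for(test_mat, test_tab))
        model.metrics = met.to_dict()
        rows.append({"tissue": tissue, **met.to_dict()})
    metrics = pd.DataFrame(rows).set_index("tissue")
    mp = out / "metrics.tsv"
    metrics.to_csv(mp, sep="\t")
    state["metrics"] = metrics
    _record(manifest, "evaluate", {"metrics": mp},
            mean_mad=float(metrics["mad"].mean()) if len(metrics) else None)


def _stage_characterize(config: RunConfig, out: Path, manifest: dict, state: dict) -> None:
    state["current"] = "characterize"
    seed = stage_seed(config.master_seed, "characterize")
    markers = state["markers"]
    if sum(len(m) for m in markers.values()) == 0:
        _record(manifest, "characterize", {}, note="no markers selected")
        return
    catalog = classify_markers(markers)
    raw = state.get("merged_raw", state["merged"])
    directions = catalog_directions(catalog, raw, state["merged_tables"])
    ratio = positive_ratio_by_occurrence(catalog, directions)
    annotation = state["annotation"]
    report: dict = {
        "n_common": len(catalog.common),
        "n_specific": len(catalog.specific),
        "occurrence_histogram": catalog.occurrence_histogram.to_dict(),
        "positive_ratio_by_occurrence": ratio["positive_fraction"].to_dict(),
    }
    outputs = {}
    cat_path = out / "marker_catalog.tsv"
    catalog.table.join(directions.rename("direction")).to_csv(cat_path, sep="\t")
    outputs["catalog"] = cat_path
    if catalog.common and catalog.specific and min(len(catalog.common), len(catalog.specific)) >= 2:
        enr = location_enrichment(catalog.common, catalog.specific, annotation,
                                  "island_relation", seed=seed)
        report["island_enrichment_p"] = enr.p_value
        report["island_enrichment_method"] = enr.method
        bg = background_location_comparison(
            catalog.table.index.tolist(), annotation, "gene_structure", seed=seed
        )
        report["gene_structure_background_p"] = bg.p_value
        cons = conservation_compare(catalog.common, catalog.specific, annotation)
        report["conservation_ks_D"] = cons.ks_statistic
        report["conservation_ks_p"] = cons.p_value
    contrasts = {}
    for tissue, mat in raw.items():
        if not markers[tissue]:
            continue
        yo = young_old_contrast(mat, state["merged_tables"][tissue],
                                markers[tissue], k=config.k_young_old)
        contrasts[tissue] = {"age_gap": yo.age_gap, "overall_beta_diff": yo.overall_diff,
                             "gap_below_40": yo.gap_below_40}
    report["young_old"] = contrasts
    rp = out / "characterization.json"
    with open(rp, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    outputs["report"] = rp
    state["characterization"] = report
    _record(manifest, "characterize", outputs,
            n_common=report["n_common"], n_specific=report["n_specific"])
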