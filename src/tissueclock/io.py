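"""Reading, writing and harmonizing beta matrices.

Matrices travel as TSV with a probe-ID index column and sample-ID header;
empty fields and ``NA`` are missing values. Harmonization intersects the
platform dialects on probe IDs, drops probes with too many missing values
(fewer than ``max_missing`` missing are kept, matching the "< 10 missing"
convention for a 27K/450K merge), mean-imputes the remainder, and
quantile-normalizes each platform batch to a uniform [0, 1] scale before
column-wise merging.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from tissueclock.containers import (
    BetaMatrix,
    ValidationError,
    validate_annotation,
    validate_sample_table,
)

MISSING_TOKENS = ("", "NA", "NaN", "nan")


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

def load_beta_matrix(path: str | Path, dialect: str = "") -> BetaMatrix:
    """Read a probes x samples TSV into a :class:`BetaMatrix`.

    The first row is the sample-ID header, the first column the probe ID.
    Missing-value tokens (empty field, ``NA``) become masked entries.
    Values outside [0, 1] and duplicated probe or sample IDs are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"malformed beta-matrix file {path}: {exc}") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        bad_line = _first_non_numeric_line(path)
        raise ValidationError(
            f"non-numeric beta value in {path} (line {bad_line}): {exc}"
        ) from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df, platform=dialect)


def _first_non_numeric_line(path: Path) -> int:
    with open(path) as fh:
        next(fh)  # header
        for lineno, line in enumerate(fh, start=2):
            for tok in line.rstrip("\n").split("\t")[1:]:
                if tok in MISSING_TOKENS:
                    continue
                try:
                    float(tok)
                except ValueError:
                    return lineno
    return -1


def save_beta_matrix(mat: BetaMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; masked entries become ``NA``."""
    # %.17g round-trips IEEE doubles exactly
    mat.values.to_csv(
        path, sep="\t", na_rep="NA", index_label="probe_id", float_format="%.17g"
    )


def load_sample_table(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    validate_sample_table(samples)
    return samples


def save_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def load_annotation(path: str | Path) -> pd.DataFrame:
    annotation = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    validate_annotation(annotation)
    return annotation


def save_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization operations
# ---------------------------------------------------------------------------

def intersect_platforms(matrices: Sequence[BetaMatrix]) -> list[BetaMatrix]:
    """Restrict every matrix to the sorted intersection of probe IDs."""
    if len(matrices) == 0:
        raise ValidationError("intersect_platforms needs at least one matrix")
    common: set[str] | None = None
    for mat in matrices:
        ids = set(mat.probe_ids)
        common = ids if common is None else common & ids
    assert common is not None
    if not common:
        raise ValidationError("platforms share no probes (empty intersection)")
    order = sorted(common)
    return [
        BetaMatrix(mat.values.loc[order], platform=mat.platform) for mat in matrices
    ]


def filter_missing(mat: BetaMatrix, max_missing: int = 10) -> BetaMatrix:
    """Keep probes with strictly fewer than ``max_missing`` masked entries.

    ``max_missing=0`` keeps only fully observed probes.
    """
    if max_missing < 0:
        raise ValidationError("max_missing must be >= 0")
    keep = mat.n_missing_per_probe() < max(max_missing, 1)
    return BetaMatrix(mat.values.loc[keep], platform=mat.platform)


def filter_missing_joint(
    matrices: Sequence[BetaMatrix], max_missing: int = 10
) -> list[BetaMatrix]:
    """Missing-value filter counting across all matrices of one tissue.

    Matrices must already share a probe index (run
    :func:`intersect_platforms` first); a probe is kept everywhere or
    dropped everywhere based on its total missing count.
    """
    _check_same_probes(matrices)
    if max_missing < 0:
        raise ValidationError("max_missing must be >= 0")
    total = sum(m.n_missing_per_probe() for m in matrices)
    keep = total < max(max_missing, 1)
    return [BetaMatrix(m.values.loc[keep], platform=m.platform) for m in matrices]


def impute_missing(mat: BetaMatrix) -> BetaMatrix:
    """Replace masked entries with the probe's observed mean."""
    all_missing = mat.values.isna().all(axis=1)
    if all_missing.any():
        bad = mat.probe_ids[all_missing].tolist()
        raise ValidationError(
            f"probes with no observed values (filter first): {bad[:5]}"
        )
    row_means = mat.values.mean(axis=1, skipna=True)
    filled = mat.values.T.fillna(row_means).T
    return BetaMatrix(filled, platform=mat.platform)


def quantile_normalize(mat: BetaMatrix) -> BetaMatrix:
    """Map each probe's values to empirical-quantile positions on [0, 1].

    Within a probe, the n sample values are replaced by
    ``(rank - 1) / (n - 1)`` with average ranks for ties, so ranks are
    preserved and the output is (empirically) uniform. A constant probe
    maps to the constant 0.5.
    """
    if mat.values.isna().any().any():
        raise ValidationError("quantile_normalize requires an imputed matrix")
    vals = mat.values.to_numpy()
    n = vals.shape[1]
    if n == 1:
        out = np.full_like(vals, 0.5)
    else:
        ranks = rankdata(vals, method="average", axis=1)
        out = (ranks - 1.0) / (n - 1.0)
    df = pd.DataFrame(out, index=mat.probe_ids, columns=mat.sample_ids)
    return BetaMatrix(df, platform=mat.platform)


def merge_datasets(
    matrices: Sequence[BetaMatrix], sample_tables: Sequence[pd.DataFrame]
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Column-wise concatenation of probe-aligned matrices.

    The merged sample table gains a ``source`` provenance column holding
    each input's platform tag (or its position when untagged).
    """
    if len(matrices) != len(sample_tables):
        raise ValidationError("matrices and sample tables must pair up")
    if len(matrices) == 0:
        raise ValidationError("nothing to merge")
    _check_same_probes(matrices)
    seen: set[str] = set()
    for mat in matrices:
        dup = seen & set(mat.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample IDs across inputs: {sorted(dup)[:5]}")
        seen |= set(mat.sample_ids)
    merged_values = pd.concat([m.values for m in matrices], axis=1)
    tables = []
    for i, (mat, tab) in enumerate(zip(matrices, sample_tables)):
        validate_sample_table(tab, mat)
        tab = tab.copy()
        tab["source"] = mat.platform or f"dataset_{i}"
        tables.append(tab)
    merged_samples = pd.concat(tables, ignore_index=True)
    tags = sorted({m.platform for m in matrices if m.platform})
    merged = BetaMatrix(merged_values, platform="+".join(tags) or "merged")
    return merged, merged_samples


def harmonize(
    matrices: Sequence[BetaMatrix],
    sample_tables: Sequence[pd.DataFrame],
    max_missing: int = 10,
    normalize: bool | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Full intersect -> filter -> impute -> normalize -> merge pipeline.

    ``normalize=None`` (default) quantile-normalizes whenever more than
    one dataset is merged, the situation the normalization exists for;
    pass True/False to force either behaviour.
    """
    mats = intersect_platforms(list(matrices))
    mats = filter_missing_joint(mats, max_missing=max_missing)
    mats = [impute_missing(m) if m.values.isna().any().any() else m for m in mats]
    if normalize is None:
        normalize = len(mats) > 1
    if normalize:
        mats = [quantile_normalize(m) for m in mats]
    return merge_datasets(mats, sample_tables)


def _check_same_probes(matrices: Iterable[BetaMatrix]) -> None:
    matrices = list(matrices)
    first = matrices[0].probe_ids
    for mat in matrices[1:]:
        if not first.equals(mat.probe_ids):
            raise ValidationError(
                "matrices do not share an identical probe index; "
                "run intersect_platforms first"
            )
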