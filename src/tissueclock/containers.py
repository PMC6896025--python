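"""In-memory containers for methylation panels.

A :class:`BetaMatrix` wraps a probes x samples :class:`pandas.DataFrame`
of methylation beta values in [0, 1]; missing measurements are NaN.
Sample tables and probe annotation are plain DataFrames with a fixed
column contract, checked by the validators below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("sample_id", "age", "tissue")
ANNOTATION_COLUMNS = (
    "probe_id",
    "gene_structure",
    "island_relation",
    "chrom",
    "start",
    "end",
    "mean_conservation",
)

GENE_STRUCTURES = ("TSS/promoter", "5'UTR", "exon", "gene body", "3'UTR", "intergenic")
ISLAND_RELATIONS = ("island", "shore", "other")


class ValidationError(ValueError):
    """A container violated its invariants."""


@dataclass
class BetaMatrix:
    """Probes x samples beta-value matrix with an explicit missing mask.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with sample-ID columns; entries are
        beta values in [0, 1] or NaN for missing measurements.
    platform
        Free-text platform tag (e.g. ``"450K"``).
    """

    values: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "probe_id"
        self.values.columns.name = None
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1] at probe {idx[i]!r}, "
                f"sample {cols[j]!r}: {vals[i, j]}"
            )

    # -- accessors -------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the measurement is missing."""
        return self.values.isna()

    def n_missing_per_probe(self) -> pd.Series:
        return self.values.isna().sum(axis=1)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy(), platform=self.platform)


def validate_sample_table(samples: pd.DataFrame, mat: BetaMatrix | None = None) -> None:
    """Check the sample-table contract (columns, finite ages, pairing)."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table lacks columns {missing}")
    if samples["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample table")
    ages = samples["age"].to_numpy(dtype=float)
    if not np.isfinite(ages).all():
        raise ValidationError("non-finite age in sample table")
    if (ages < 0).any():
        raise ValidationError("negative age in sample table")
    if mat is not None:
        table_ids = set(samples["sample_id"])
        mat_ids = set(mat.sample_ids)
        if table_ids != mat_ids:
            raise ValidationError(
                "sample table and beta matrix disagree on sample IDs "
                f"(only-in-table: {sorted(table_ids - mat_ids)[:3]}, "
                f"only-in-matrix: {sorted(mat_ids - table_ids)[:3]})"
            )


def validate_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation lacks columns {missing}")
    if annotation["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe_id in annotation")
    if (annotation["start"] >= annotation["end"]).any():
        raise ValidationError("annotation region with start >= end")
    cons = annotation["mean_conservation"].to_numpy(dtype=float)
    if ((cons < 0) | (cons > 1)).any():
        raise ValidationError("mean_conservation outside [0, 1]")


def ages_for(mat: BetaMatrix, samples: pd.DataFrame) -> np.ndarray:
    """Chronological ages aligned to the matrix's sample order."""
    validate_sample_table(samples, mat)
    lookup = samples.set_index("sample_id")["age"]
    return lookup.loc[mat.sample_ids].to_numpy(dtype=float)
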