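"""Per-probe age-association filtering.

Fits the univariate beta-on-age regression for every harmonized probe,
applies Benjamini-Hochberg FDR over the probe family, and keeps probes
with q < 0.05 as candidates for stability selection.
"""

from pathlib import Path

import pandas as pd

from tissueclock import io as mio
from tissueclock.association import associate_all

OUT = Path("results/analysis")
TISSUES = ("tissue_1", "tissue_2", "tissue_3")
FDR = 0.05


def main() -> None:
    for tissue in TISSUES:
        mat = mio.load_beta_matrix(OUT / f"{tissue}_merged.tsv")
        samples = pd.read_csv(OUT / f"{tissue}_merged_samples.tsv", sep="\t")
        res = associate_all(mat, samples)
        res["selected"] = res["q_value"] < FDR
        res.to_csv(OUT / f"{tissue}_assoc.tsv", sep="\t", index_label="probe_id")
        n_sel = int(res["selected"].sum())
        print(f"{tissue}: {n_sel} of {len(res)} probes pass FDR < {FDR} "
              f"(min q = {res['q_value'].min():.2e})")


if __name__ == "__main__":
    main()
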