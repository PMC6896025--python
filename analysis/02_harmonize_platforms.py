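"""Harmonize the two platform dialects of each tissue.

Intersects probe sets, drops probes with 10 or more missing values,
mean-imputes the rest, quantile-normalizes each platform batch and
merges into one matrix per tissue. Writes both the normalized matrix
(used for modeling) and the raw-beta merge (used for direction and
young/old analyses).
"""

from pathlib import Path

from tissueclock import io as mio

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")
TISSUES = ("tissue_1", "tissue_2", "tissue_3")


def main() -> None:
    for tissue in TISSUES:
        samples = mio.load_sample_table(DATA / f"{tissue}_samples.tsv")
        dialects, tabs = [], []
        for dialect in ("27K", "450K"):
            mat = mio.load_beta_matrix(DATA / f"{tissue}_{dialect}.tsv", dialect)
            if mat.shape[1]:
                dialects.append(mat)
                tabs.append(samples[samples["sample_id"].isin(mat.sample_ids)])
        merged, merged_tab = mio.harmonize(dialects, tabs, max_missing=10)
        raw, _ = mio.harmonize(dialects, tabs, max_missing=10, normalize=False)
        mio.save_beta_matrix(merged, OUT / f"{tissue}_merged.tsv")
        mio.save_beta_matrix(raw, OUT / f"{tissue}_merged_raw.tsv")
        merged_tab.to_csv(OUT / f"{tissue}_merged_samples.tsv", sep="\t", index=False)
        dropped = dialects[0].shape[0] + dialects[1].shape[0]
        print(f"{tissue}: merged {merged.shape[0]} probes x {merged.shape[1]} samples "
              f"(27K: {dialects[0].shape}, 450K: {dialects[1].shape})")


if __name__ == "__main__":
    main()
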