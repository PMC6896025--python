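"""Simulate the multi-tissue methylation panel used by the analysis.

Generates three tissue cohorts (150 samples each, 2,000 probes) with 20
tissue-common and 15 per-tissue-specific planted aging CpGs, exports each
tissue as two platform-dialect TSVs (a 27K-style probe subset and the
full 450K-style universe), and writes the sample tables, annotation and
planted ground truth under results/analysis/data/.
"""

from pathlib import Path

from tissueclock import io as mio
from tissueclock.simulate import SimConfig, export_platform_dialects, generate_panel

OUT = Path("results/analysis/data")
SEED = 11


def main() -> None:
    cfg = SimConfig(seed=SEED)
    mats, tables, annotation, truth = generate_panel(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    for mat, tab in zip(mats, tables):
        tissue = str(tab["tissue"].iloc[0])
        p27, p450 = export_platform_dialects(mat, tab, truth, cfg, OUT, tissue)
        mio.save_sample_table(tab, OUT / f"{tissue}_samples.tsv")
        print(f"{tissue}: {mat.shape[0]} probes x {mat.shape[1]} samples "
              f"-> {p27.name} ({cfg.platform_split:.0%} of samples), {p450.name}")
    mio.save_annotation(annotation, OUT / "annotation.tsv")
    gt = truth.labels.to_frame().join(truth.directions).join(truth.slopes)
    gt.to_csv(OUT / "ground_truth.tsv", sep="\t")
    counts = truth.labels.value_counts()
    print(f"planted: {counts['common']} common + {counts['specific']} specific "
          f"markers among {cfg.n_probes} probes (seed {SEED})")


if __name__ == "__main__":
    main()
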