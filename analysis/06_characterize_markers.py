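"""Characterize tissue-common vs tissue-specific aging markers.

Groups the per-tissue marker lists by occurrence (>= 2 tissue models =
common), assigns positive/negative aging directions from raw training
betas, and runs the group comparisons: positive-fraction by occurrence,
CpG island/shore enrichment (Fisher), gene-structure background
comparison, conservation (two-sample KS), the five-oldest vs
five-youngest contrast, and the per-tissue slope of the top common
marker. Results land in results/analysis/characterization/.
"""

import json
from pathlib import Path

import pandas as pd

from tissueclock import io as mio
from tissueclock.characterize import (
    background_location_comparison,
    catalog_directions,
    classify_markers,
    conservation_compare,
    location_enrichment,
    marker_slope_by_tissue,
    positive_ratio_by_occurrence,
    young_old_contrast,
)
from tissueclock.stability import select_markers

OUT = Path("results/analysis")
REPORT = OUT / "characterization"
TISSUES = ("tissue_1", "tissue_2", "tissue_3")
SEED = 43


def main() -> None:
    REPORT.mkdir(parents=True, exist_ok=True)
    annotation = mio.load_annotation(OUT / "data" / "annotation.tsv")
    raw_mats, tabs, per_tissue = {}, {}, {}
    for tissue in TISSUES:
        raw_mats[tissue] = mio.load_beta_matrix(OUT / f"{tissue}_merged_raw.tsv")
        tabs[tissue] = pd.read_csv(OUT / f"{tissue}_merged_samples.tsv", sep="\t")
        stab = pd.read_csv(OUT / f"{tissue}_markers.tsv", sep="\t", index_col="probe_id")
        per_tissue[tissue] = select_markers(stab)

    catalog = classify_markers(per_tissue)
    directions = catalog_directions(catalog, raw_mats, tabs)
    catalog.table.join(directions.rename("direction")).to_csv(
        REPORT / "catalog.tsv", sep="\t"
    )
    catalog.occurrence_histogram.to_csv(REPORT / "occurrence_histogram.tsv", sep="\t")
    print(f"{len(catalog.common)} tissue-common and {len(catalog.specific)} "
          f"tissue-specific markers "
          f"(occurrence histogram {catalog.occurrence_histogram.to_dict()})")

    ratio = positive_ratio_by_occurrence(catalog, directions)
    ratio.to_csv(REPORT / "positive_ratio_by_occurrence.tsv", sep="\t")
    print("positive-ageCG fraction by occurrence:",
          {k: round(v, 3) for k, v in ratio["positive_fraction"].items()})

    summary = {"n_common": len(catalog.common), "n_specific": len(catalog.specific)}
    enr = location_enrichment(catalog.common, catalog.specific, annotation,
                              "island_relation", seed=SEED)
    enr.table.to_csv(REPORT / "island_enrichment.tsv", sep="\t")
    summary["island_enrichment_p"] = enr.p_value
    print(f"island/shore contrast common vs specific: p = {enr.p_value:.4g} "
          f"({enr.method})")

    bg = background_location_comparison(catalog.table.index.tolist(), annotation,
                                        "gene_structure", seed=SEED)
    summary["gene_structure_background_p"] = bg.p_value
    print(f"gene-structure markers vs probe universe: p = {bg.p_value:.4g}")

    cons = conservation_compare(catalog.common, catalog.specific, annotation)
    summary["conservation_ks_D"] = cons.ks_statistic
    summary["conservation_ks_p"] = cons.p_value
    print(f"conservation common vs specific: KS D = {cons.ks_statistic:.3f}, "
          f"p = {cons.p_value:.4g}")

    contrasts = {}
    for tissue in TISSUES:
        yo = young_old_contrast(raw_mats[tissue], tabs[tissue], per_tissue[tissue], k=5)
        contrasts[tissue] = {"age_gap": yo.age_gap, "beta_diff": yo.overall_diff}
        print(f"{tissue}: 5 oldest vs 5 youngest gap {yo.age_gap:.0f}y, "
              f"mean marker beta difference {yo.overall_diff:+.3f}")
    summary["young_old"] = contrasts

    # slope of the most widely shared marker across tissues
    top = catalog.table.sort_values(["occurrence"], ascending=False).index[0]
    slopes = marker_slope_by_tissue(top, raw_mats, tabs)
    slopes.to_csv(REPORT / "top_marker_slopes.tsv", sep="\t")
    summary["top_common_marker"] = top
    print(f"per-tissue slope of {top} (beta/yr):",
          {t: round(s, 5) for t, s in slopes["slope"].items()})

    with open(REPORT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
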