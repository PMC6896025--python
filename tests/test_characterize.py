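"""Marker grouping, direction, enrichment, conservation, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueclock.characterize import (
    CharacterizationError,
    _fisher_rxc_exact,
    _fisher_rxc_montecarlo,
    age_direction,
    background_location_comparison,
    catalog_directions,
    classify_markers,
    conservation_compare,
    location_enrichment,
    marker_slope_by_tissue,
    mean_region_conservation,
    positive_ratio_by_occurrence,
    young_old_contrast,
)
from tissueclock.containers import BetaMatrix


def _annotation(ids, island=None, structure=None, conservation=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "probe_id": ids,
            "gene_structure": structure if structure is not None else ["exon"] * n,
            "island_relation": island if island is not None else ["island"] * n,
            "chrom": "chr1",
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 50,
            "mean_conservation": conservation if conservation is not None else [0.5] * n,
        }
    )


class TestClassifyMarkers:
    def test_marker_in_all_nine_lists_is_common(self):
        lists = {f"t{i}": ["cgX", f"cg{i}"] for i in range(9)}
        cat = classify_markers(lists)
        assert cat.table.loc["cgX", "occurrence"] == 9
        assert cat.table.loc["cgX", "group"] == "common"

    def test_marker_in_one_list_is_specific(self):
        cat = classify_markers({"a": ["cg1"], "b": ["cg2"]})
        assert (cat.table["group"] == "specific").all()

    def test_occurrence_two_is_common_by_default(self):
        cat = classify_markers({"a": ["cgX"], "b": ["cgX"], "c": []})
        assert cat.table.loc["cgX", "group"] == "common"

    def test_strict_reading_leaves_occurrence_two_intermediate(self):
        cat = classify_markers(
            {"a": ["cgX"], "b": ["cgX"], "c": []}, strict_more_than_two=True
        )
        assert cat.table.loc["cgX", "group"] == "intermediate"

    def test_partition_complete_and_histogram_reconciles(self):
        lists = {
            "a": ["cg1", "cg2", "cg3"],
            "b": ["cg2", "cg3", "cg4"],
            "c": ["cg3"],
        }
        cat = classify_markers(lists)
        assert len(cat.common) + len(cat.specific) == len(cat.table)
        assert cat.occurrence_histogram.sum() == len(cat.table)
        assert cat.occurrence_histogram.to_dict() == {1: 2, 2: 1, 3: 1}

    def test_fewer_than_two_tissues_rejected(self):
        with pytest.raises(CharacterizationError):
            classify_markers({"a": ["cg1"]})

    def test_empty_union_rejected(self):
        with pytest.raises(CharacterizationError, match="empty"):
            classify_markers({"a": [], "b": []})


class TestAgeDirection:
    def test_planted_directions_recovered(self, harmonized_tissue):
        mat, samples, _, truth = harmonized_tissue
        tissue = samples["tissue"].iloc[0]
        markers = [m for m in truth.markers_for_tissue(tissue) if m in mat.probe_ids]
        dirs = age_direction(mat, samples, markers)
        agree = (
            dirs["direction"].to_numpy() == truth.directions.loc[markers].to_numpy()
        )
        assert agree.mean() >= 0.99

    def test_constant_marker_flagged_ambiguous(self, tiny_samples):
        values = pd.DataFrame(
            [[0.5, 0.5, 0.5]], index=["cgflat"], columns=["s1", "s2", "s3"]
        )
        dirs = age_direction(BetaMatrix(values), tiny_samples, ["cgflat"])
        assert dirs.loc["cgflat", "direction"] == 0
        assert bool(dirs.loc["cgflat", "ambiguous"])


def test_positive_ratio_by_occurrence_all_positive():
    cat = classify_markers({"a": ["cg1", "cg2"], "b": ["cg2"]})
    directions = pd.Series({"cg1": 1, "cg2": 1})
    tab = positive_ratio_by_occurrence(cat, directions)
    assert (tab["positive_fraction"] == 1.0).all()


def test_positive_ratio_recovers_planted_gradient():
    """Markers planted with rising positive fraction by occurrence."""
    rng = np.random.default_rng(0)
    lists = {"a": [], "b": [], "c": []}
    directions = {}
    fracs = {1: 0.3, 2: 0.6, 3: 0.9}
    for occ, frac in fracs.items():
        for i in range(40):
            m = f"cg_{occ}_{i}"
            for t in list(lists)[:occ]:
                lists[t].append(m)
            directions[m] = 1 if i < round(frac * 40) else -1
    cat = classify_markers(lists)
    tab = positive_ratio_by_occurrence(cat, pd.Series(directions))
    est = tab["positive_fraction"]
    assert est.loc[1] < est.loc[2] < est.loc[3]
    for occ, frac in fracs.items():
        assert est.loc[occ] == pytest.approx(frac, abs=0.02)


class TestLocationEnrichment:
    def test_identical_proportions_give_null_result(self):
        ids_a = [f"a{i}" for i in range(20)]
        ids_b = [f"b{i}" for i in range(20)]
        island = ["island"] * 5 + ["shore"] * 15 + ["island"] * 5 + ["shore"] * 15
        ann = _annotation(ids_a + ids_b, island=island)
        res = location_enrichment(ids_a[:20], ids_b, ann)
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_2x2_matches_frozen_hypergeometric_enumeration(self):
        # table [[8,2],[3,7]]: oracle p = 0.0697785187 (computed before build)
        ids_a = [f"a{i}" for i in range(10)]
        ids_b = [f"b{i}" for i in range(10)]
        island = ["island"] * 8 + ["shore"] * 2 + ["island"] * 3 + ["shore"] * 7
        ann = _annotation(ids_a + ids_b, island=island)
        res = location_enrichment(ids_a, ids_b, ann)
        assert res.p_value == pytest.approx(0.0697785187, rel=1e-8)
        assert res.method == "fisher-exact-2x2"

    def test_rxc_enumeration_matches_montecarlo(self):
        table = np.array([[6, 2, 4], [1, 7, 3]])
        p_exact = _fisher_rxc_exact(table)
        p_mc = _fisher_rxc_montecarlo(table, seed=0)
        assert p_exact is not None
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_rxc_enumeration_reduces_to_2x2_fisher(self):
        table = np.array([[8, 2], [3, 7]])
        assert _fisher_rxc_exact(table) == pytest.approx(0.0697785187, rel=1e-8)

    def test_empty_group_rejected(self):
        ann = _annotation(["a0"])
        with pytest.raises(CharacterizationError, match="empty"):
            location_enrichment([], ["a0"], ann)

    def test_unannotated_probe_reported(self):
        ann = _annotation(["a0"])
        with pytest.raises(CharacterizationError, match="cg_missing"):
            location_enrichment(["cg_missing"], ["a0"], ann)


class TestBackgroundComparison:
    def test_extreme_concentration_gives_small_p(self):
        ids = [f"cg{i}" for i in range(60)]
        structure = ["gene body"] * 20 + ["exon"] * 40
        ann = _annotation(ids, structure=structure)
        res = background_location_comparison(ids[:20], ann)
        # markers are all gene-body, background all exon: near-minimal p
        assert res.p_value < 1e-6

    def test_uniformly_drawn_markers_show_no_enrichment(self):
        rng = np.random.default_rng(3)
        ids = [f"cg{i}" for i in range(400)]
        structure = rng.choice(["gene body", "exon", "intergenic"], size=400)
        ann = _annotation(ids, structure=structure)
        ps = []
        for rep in range(20):
            markers = rng.choice(ids, size=50, replace=False)
            ps.append(background_location_comparison(list(markers), ann, seed=rep).p_value)
        # null p-values should not pile up near zero
        assert np.mean(np.asarray(ps) < 0.05) <= 0.25

    def test_empty_marker_set_rejected(self):
        ann = _annotation(["a0"])
        with pytest.raises(CharacterizationError):
            background_location_comparison([], ann)


class TestConservation:
    def test_identical_lists_d_zero(self):
        ids = [f"cg{i}" for i in range(6)]
        ann = _annotation(ids, conservation=[0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        res = conservation_compare(ids[:3], ids[3:], ann)
        assert res.ks_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        ids = [f"cg{i}" for i in range(6)]
        ann = _annotation(ids, conservation=[0.1, 0.15, 0.2, 0.8, 0.85, 0.9])
        res = conservation_compare(ids[:3], ids[3:], ann)
        assert res.ks_statistic == 1.0

    def test_frozen_ecdf_sup_example(self):
        # [0.1,0.2,0.3] vs [0.2,0.4,0.6]: brute-force sup = 2/3
        ids = [f"cg{i}" for i in range(6)]
        ann = _annotation(ids, conservation=[0.1, 0.2, 0.3, 0.2, 0.4, 0.6])
        res = conservation_compare(ids[:3], ids[3:], ann)
        assert res.ks_statistic == pytest.approx(2 / 3, rel=1e-12)

    def test_ks_statistic_equals_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            na, nb = rng.integers(3, 50, size=2)
            a = rng.random(na)
            b = rng.random(nb) ** 2
            ids = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
            ann = _annotation(ids, conservation=np.concatenate([a, b]))
            res = conservation_compare(ids[:na], ids[na:], ann)
            pooled = np.concatenate([a, b])
            d_brute = max(
                abs((a <= t).mean() - (b <= t).mean()) for t in pooled
            )
            assert res.ks_statistic == pytest.approx(d_brute, abs=1e-12)

    def test_small_group_rejected(self):
        ann = _annotation(["a0", "a1", "a2"])
        with pytest.raises(CharacterizationError):
            conservation_compare(["a0"], ["a1", "a2"], ann)


def test_mean_region_conservation():
    assert mean_region_conservation([0.5, 0.5, 0.5]) == 0.5
    assert mean_region_conservation([0.1, 0.2, 0.3]) == pytest.approx(0.2)
    assert mean_region_conservation([0.3, 0.2, 0.1]) == pytest.approx(0.2)
    with pytest.raises(CharacterizationError, match="empty"):
        mean_region_conservation([])


class TestYoungOld:
    def test_positive_markers_show_positive_difference(self, harmonized_tissue):
        mat, samples, _, truth = harmonized_tissue
        tissue = samples["tissue"].iloc[0]
        markers = [
            m
            for m in truth.markers_for_tissue(tissue)
            if m in mat.probe_ids and truth.directions[m] > 0
        ]
        res = young_old_contrast(mat, samples, markers, k=5)
        assert res.overall_diff > 0
        assert res.age_gap > 40
        assert not res.gap_below_40

    def test_null_markers_difference_near_zero(self, harmonized_tissue):
        mat, samples, _, truth = harmonized_tissue
        nulls = [m for m in truth.probe_ids
                 if truth.labels[m] == "null" and m in mat.probe_ids][:50]
        res = young_old_contrast(mat, samples, nulls, k=5)
        # CLT scale: noise_sd / sqrt(k * n_markers), generous factor
        bound = 4 * 0.02 / math.sqrt(5 * len(nulls)) + 0.01
        assert abs(res.overall_diff) < bound

    def test_boundary_k_accepted_and_overflow_rejected(self, tiny_samples):
        values = pd.DataFrame(
            [[0.1, 0.2, 0.4]], index=["cgA"], columns=["s1", "s2", "s3"]
        )
        mat = BetaMatrix(values)
        with pytest.raises(CharacterizationError):
            young_old_contrast(mat, tiny_samples, ["cgA"], k=2)
        res = young_old_contrast(mat, tiny_samples, ["cgA"], k=1)
        assert res.age_gap == pytest.approx(50.0)
        assert res.per_marker_diff["cgA"] == pytest.approx(0.3)


class TestSlopeByTissue:
    def test_planted_per_tissue_slopes_recovered(self, small_panel):
        cfg, (mats, tables, _, truth) = small_panel
        tissues = [t["tissue"].iloc[0] for t in tables]
        mat_map = {t: m for t, m in zip(tissues, mats)}
        # drop missing entries per tissue by imputing first
        from tissueclock.io import impute_missing

        mat_map = {t: impute_missing(m) for t, m in mat_map.items()}
        tab_map = {t: tab for t, tab in zip(tissues, tables)}
        probe = truth.markers("common")[0]
        res = marker_slope_by_tissue(probe, mat_map, tab_map)
        for tissue in tissues:
            planted = truth.slopes.loc[probe, tissue]
            row = res.loc[tissue]
            assert abs(row["slope"] - planted) <= 3 * row["stderr"]

    def test_identical_datasets_identical_slopes(self, harmonized_tissue):
        mat, samples, _, _ = harmonized_tissue
        probe = mat.probe_ids[0]
        res = marker_slope_by_tissue(
            probe, {"a": mat, "b": mat}, {"a": samples, "b": samples}
        )
        assert res.loc["a", "slope"] == res.loc["b", "slope"]

    def test_missing_probe_rejected(self, harmonized_tissue):
        mat, samples, _, _ = harmonized_tissue
        with pytest.raises(CharacterizationError):
            marker_slope_by_tissue("cg_nope", {"a": mat}, {"a": samples})


def test_catalog_directions_majority_vote(small_panel):
    cfg, (mats, tables, _, truth) = small_panel
    from tissueclock.io import impute_missing

    tissues = [t["tissue"].iloc[0] for t in tables]
    mat_map = {t: impute_missing(m) for t, m in zip(tissues, mats)}
    tab_map = dict(zip(tissues, tables))
    per_tissue = {
        t: [m for m in truth.markers_for_tissue(t) if m in mat_map[t].probe_ids]
        for t in tissues
    }
    cat = classify_markers(per_tissue)
    dirs = catalog_directions(cat, mat_map, tab_map)
    planted = truth.directions.loc[dirs.index]
    assert (dirs == planted).mean() >= 0.95
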