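"""Overlap indices, classification rules, null models and the pair table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avianiche.community_model import AbundanceCurve
from avianiche.niche_metrics import (
    OverlapResult,
    body_size_cv,
    build_pair_table,
    classify_elevation_pair,
    detection_sites,
    elevation_overlap,
    latent_co_occurrence,
    null_pair_distribution,
    pianka_overlap,
    spatial_site_index,
)
from avianiche.reference import FAMILY_MASSES_G


def curve(values, grid=None, standardized=True):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, len(values))
    return AbundanceCurve(grid=grid, grid_m=grid * 1000 + 1800, values=values,
                          standardized=standardized)


class TestElevationOverlap:
    def test_identical_curves_full_overlap(self):
        g = np.linspace(0, 1, 501)
        c = curve(np.exp(-((g - 0.5) ** 2) * 8), g)
        res = elevation_overlap(c, c)
        assert res.n_ab == pytest.approx(1.0)
        assert res.n_ba == pytest.approx(1.0)

    def test_disjoint_supports_no_overlap(self):
        g = np.linspace(0, 1, 1001)
        a = curve(np.where(g < 0.45, 1.0, 0.0), g)
        b = curve(np.where(g > 0.55, 1.0, 0.0), g)
        res = elevation_overlap(a, b)
        assert res.n_ab == 0.0 and res.n_ba == 0.0

    def test_half_window_overlap(self):
        # A constant 1 on [0,1]; B = 1 on [0, 0.5]: N_AB=0.5, N_BA=1
        g = np.linspace(0, 1, 1001)
        a = curve(np.ones_like(g), g)
        b = curve(np.where(g <= 0.5, 1.0, 0.0), g)
        res = elevation_overlap(a, b)
        assert res.n_ab == pytest.approx(0.5, abs=1e-3)
        assert res.n_ba == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_of_shared_area(self):
        rng = np.random.default_rng(2)
        g = np.linspace(0, 1, 301)
        a = curve(np.exp(-((g - 0.3) ** 2) * 10), g)
        b = curve(np.exp(-((g - 0.7) ** 2) * 6), g)
        assert elevation_overlap(a, b).ov == elevation_overlap(b, a).ov

    def test_grid_refinement_stable(self):
        def curves(n):
            g = np.linspace(0, 1, n)
            return (curve(np.exp(-((g - 0.4) ** 2) * 12), g),
                    curve(np.exp(-((g - 0.6) ** 2) * 9), g))
        coarse = elevation_overlap(*curves(1000))
        fine = elevation_overlap(*curves(10_000))
        assert abs(coarse.n_ab - fine.n_ab) < 1e-3

    def test_mismatched_grids_rejected(self):
        a = curve(np.ones(10))
        b = curve(np.ones(11))
        with pytest.raises(ValueError):
            elevation_overlap(a, b)

    def test_unstandardized_rejected(self):
        a = curve(np.ones(10), standardized=False)
        with pytest.raises(ValueError):
            elevation_overlap(a, a)


class TestClassification:
    @pytest.mark.parametrize("n_ab,n_ba,want", [
        (0.08, 0.03, "no-overlap"),   # published turaco pair
        (0.6, 0.7, "similar"),
        (0.8, 0.3, "partial"),
        (0.5, 0.5, "similar"),        # boundary: at least 50%
        (0.09, 0.11, "partial"),
        (0.0, 0.0, "no-overlap"),
    ])
    def test_rule(self, n_ab, n_ba, want):
        res = OverlapResult(n_ab=n_ab, n_ba=n_ba, ov=0.1, t_a=1.0, t_b=1.0)
        assert classify_elevation_pair(res) == want


class TestPianka:
    def test_identical_compositions(self):
        assert pianka_overlap([0.2, 0.5, 0.3], [0.2, 0.5, 0.3]) == pytest.approx(1.0)

    def test_disjoint_compositions(self):
        assert pianka_overlap([1, 0, 0], [0, 0.4, 0.6]) == 0.0

    def test_half_shared(self):
        # 0.25 / sqrt(0.5 * 0.5) = 0.5
        assert pianka_overlap([0.5, 0.5, 0.0], [0.0, 0.5, 0.5]) == pytest.approx(0.5)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6),
        st.floats(0.1, 50.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetric_scale_invariant_bounded(self, pa, pb, c):
        n = min(len(pa), len(pb))
        pa, pb = np.array(pa[:n]) + 1e-3, np.array(pb[:n]) + 1e-3
        o = pianka_overlap(pa, pb)
        assert 0.0 <= o <= 1.0 + 1e-12
        assert o == pytest.approx(pianka_overlap(pb, pa), abs=1e-12)
        assert o == pytest.approx(pianka_overlap(c * pa, pb), abs=1e-9)

    def test_one_iff_proportional(self):
        assert pianka_overlap([0.2, 0.8], [0.1, 0.4]) == pytest.approx(1.0)
        assert pianka_overlap([0.2, 0.8], [0.3, 0.7]) < 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pianka_overlap([0, 0], [1, 0])


class TestSpatialSiteIndex:
    def test_identical_sets(self):
        assert spatial_site_index({1, 2}, {1, 2}).ssi == 1.0

    def test_disjoint_sets(self):
        assert spatial_site_index({1, 2}, {3}).ssi == 0.0

    def test_counts(self):
        res = spatial_site_index({1, 2, 3, 4}, {3, 4, 5})
        assert (res.ssi, res.shared, res.union) == (0.4, 2, 5)

    def test_relabel_invariant(self):
        a, b = {1, 2, 3, 4}, {3, 4, 5}
        relabel = {1: "x", 2: "y", 3: "z", 4: "w", 5: "v"}
        res1 = spatial_site_index(a, b)
        res2 = spatial_site_index({relabel[i] for i in a}, {relabel[i] for i in b})
        assert res1.ssi == res2.ssi

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spatial_site_index(set(), set())


class TestBodySizeCV:
    @pytest.mark.parametrize("family,expect", [
        ("Lybiidae", 111), ("Cuculidae", 88),
        ("Nectariniidae", 39), ("Cisticolidae", 26),
    ])
    def test_published_family_values(self, family, expect):
        masses = list(FAMILY_MASSES_G[family].values())
        assert round(body_size_cv(masses)) == expect

    def test_equal_masses_zero(self):
        assert body_size_cv([5.0, 5.0, 5.0]) == 0.0

    def test_scale_invariant(self):
        m = [13.1, 10.7, 76.1]
        assert body_size_cv(m) == pytest.approx(body_size_cv([3.3 * x for x in m]))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            body_size_cv([10.0])


class TestLatentCoOccurrence:
    def test_always_together(self):
        n = np.ones((4, 6), dtype=int)
        assert latent_co_occurrence(n, n) == 1.0

    def test_one_always_absent(self):
        a = np.ones((4, 6), dtype=int)
        b = np.zeros((4, 6), dtype=int)
        assert latent_co_occurrence(a, b) == 0.0

    def test_hand_counted_toy(self):
        # draw 1: both at site0 only, either at sites 0,1,2 -> 1/3
        # draw 2: both at sites 0,1, either at 0,1 -> 1
        a = np.array([[2, 1, 0], [1, 3, 0]])
        b = np.array([[1, 0, 5], [2, 1, 0]])
        assert latent_co_occurrence(a, b) == pytest.approx((1 / 3 + 1.0) / 2)

    def test_empty_draws_skipped(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[1, 1], [0, 0]])
        with pytest.warns(UserWarning, match="skipped"):
            assert latent_co_occurrence(a, b) == pytest.approx(0.5)


class TestNullPairDistribution:
    FAMILIES = {"a": "f1", "b": "f1", "c": "f2", "d": "f2"}

    def test_exhaustive_enumeration(self):
        # 4 cross-family pairs: (a,c),(a,d),(b,c),(b,d)
        vals = {("a", "c"): 0.1, ("a", "d"): 0.9, ("b", "c"): 0.2, ("b", "d"): 0.8}
        res = null_pair_distribution(
            lambda x, y: vals[(x, y)], list("abcd"), self.FAMILIES,
            criterion=lambda v: v <= 0.5,
        )
        assert res.n_draws == 4
        assert res.proportion == 0.5  # hand enumeration: 2 of 4 pairs <= 0.5

    def test_singleton_families_use_all_pairs(self):
        fams = {s: s for s in "abcd"}  # every species its own family
        res = null_pair_distribution(lambda x, y: 1.0, list("abcd"), fams)
        assert res.n_draws == 6  # C(4,2)

    def test_constant_metric_degenerate(self):
        res = null_pair_distribution(
            lambda x, y: 0.7, list("abcd"), self.FAMILIES,
            criterion=lambda v: v > 0.5,
        )
        assert res.proportion == 1.0

    def test_reproducible(self):
        species = [f"s{i}" for i in range(30)]
        fams = {s: f"f{i % 5}" for i, s in enumerate(species)}
        rng = np.random.default_rng(0)
        vals = {s: rng.random() for s in species}
        run = lambda: null_pair_distribution(
            lambda x, y: vals[x] * vals[y], species, fams, n_draws=50, seed=42
        )
        np.testing.assert_array_equal(run().draws, run().draws)

    def test_no_cross_family_pair(self):
        with pytest.raises(ValueError):
            null_pair_distribution(lambda x, y: 0, ["a", "b"],
                                   {"a": "f", "b": "f"})


class TestBuildPairTable:
    @staticmethod
    def inputs():
        g = np.linspace(0, 1, 501)
        curves = {
            # f1: a/b strongly overlapping; c disjoint from both
            "a": curve(np.exp(-((g - 0.4) ** 2) * 8), g),
            "b": curve(np.exp(-((g - 0.45) ** 2) * 8), g),
            "c": curve(np.where(g > 0.9, 1.0, 1e-9), g),
            # f2: single species, contributes no pairs
            "d": curve(np.ones_like(g), g),
        }
        taxonomy = {"a": "f1", "b": "f1", "c": "f1", "d": "f2"}
        rows = []
        strata = {"a": [0.9, 0.1, 0, 0, 0], "b": [0.0, 0.1, 0.9, 0, 0],
                  "c": [0.8, 0.2, 0, 0, 0], "d": [1.0, 0, 0, 0, 0]}
        for sp in "abcd":
            row = {"species": sp, "family": taxonomy[sp], "mass_g": 10.0,
                   "activity": "diurnal", "diet_1": 0.5, "diet_2": 0.5}
            row.update({f"strata_{i+1}": v for i, v in enumerate(strata[sp])})
            rows.append(row)
        from avianiche.data_prep import TraitTable
        traits = TraitTable(pd.DataFrame(rows))
        detections = {"a": {1, 2, 3}, "b": {3, 4}, "c": {9}, "d": {1}}
        return curves, traits, detections, taxonomy

    def test_pair_combinatorics(self):
        curves, traits, detections, taxonomy = self.inputs()
        table = build_pair_table(curves, traits, detections, taxonomy)
        # family f1 has 3 species -> C(3,2)=3 rows; f2 has 1 -> none
        assert len(table) == 3
        assert set(table["family"]) == {"f1"}

    def test_labels_follow_rule(self):
        curves, traits, detections, taxonomy = self.inputs()
        table = build_pair_table(curves, traits, detections, taxonomy).set_index(
            ["species_a", "species_b"]
        )
        ab = table.loc[("a", "b")]
        assert ab["elev_category"] == "similar"
        # similar elevation + low strata overlap -> strata,spatial
        assert ab["partitioning"] == "strata,spatial"
        ac = table.loc[("a", "c")]
        assert ac["elev_category"] != "similar"
        assert "elev" in ac["partitioning"]
        assert "spatial" not in ac["partitioning"]

    def test_ssi_values(self):
        curves, traits, detections, taxonomy = self.inputs()
        table = build_pair_table(curves, traits, detections, taxonomy).set_index(
            ["species_a", "species_b"]
        )
        assert table.loc[("a", "b"), "ssi"] == pytest.approx(1 / 4)

    def test_missing_traits_flagged(self):
        curves, traits, detections, taxonomy = self.inputs()
        t = traits.table[traits.table["species"] != "b"].reset_index(drop=True)
        from avianiche.data_prep import TraitTable
        table = build_pair_table(curves, TraitTable(t), detections, taxonomy)
        row = table[(table["species_a"] == "a") & (table["species_b"] == "b")]
        assert row["missing"].iloc[0] == "traits"
        assert np.isnan(row["pianka_diet"].iloc[0])

    def test_threshold_monotonicity(self):
        curves, traits, detections, taxonomy = self.inputs()
        n_similar = []
        for thr in (0.5, 0.9):
            t = build_pair_table(curves, traits, detections, taxonomy,
                                 thresholds={"similar": thr})
            n_similar.append((t["elev_category"] == "similar").sum())
        assert n_similar[1] <= n_similar[0]


def test_detection_sites_from_survey(small_survey):
    ds, _ = small_survey
    sites = detection_sites(ds)
    sp = ds.species[0]
    n = ds.n_js[:, 0]
    want = set(ds.sites["site_id"].to_numpy()[n > 0])
    assert sites[sp] == want
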