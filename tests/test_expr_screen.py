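import numpy as np
import pandas as pd
import pytest

from clonaltrace import expr_screen as es
from clonaltrace import synthetic_data as sd


@pytest.fixture(scope="module")
def bundle():
    cfg = sd.ExprSimConfig(n_genes=80, n_planted_trait_genes=8,
                           n_planted_degs=12, seed=42)
    return sd.generate_expression(cfg)


class TestCallDegs:
    def test_thresholds_on_supplied_de_table(self):
        de = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3", "g4"],
                "log2fc": [0.9, 1.0, -1.4, 2.5],
                "p": [0.001, 0.01, 0.04, 0.2],
            }
        )
        passing = es.call_degs(pd.DataFrame(), de_table=de)
        # |log2FC| ≥ 1 AND p < 0.05: g1 fails on fold change, g4 on p
        assert set(passing["gene"]) == {"g2", "g3"}

    def test_identical_groups_yield_no_degs(self, rng):
        fpkm = pd.DataFrame(
            np.tile(rng.uniform(5, 50, size=(30, 1)), (1, 6)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=fpkm.columns)
        assert len(es.call_degs(fpkm, groups)) == 0

    def test_missing_replicates_rejected(self, rng):
        fpkm = pd.DataFrame(
            rng.uniform(1, 10, (5, 3)), columns=["s1", "s2", "s3"]
        )
        groups = pd.Series(["A", "A", "B"], index=fpkm.columns)
        with pytest.raises(ValueError, match="two replicates"):
            es.call_degs(fpkm, groups)

    def test_planted_deg_recall_across_simulations(self):
        """Genes planted with a 3-log₂ shift at low dispersion are
        recalled at ≥ 0.95 by the stand-in caller (200 seeded runs)."""
        hits = total = 0
        for seed in range(200):
            cfg = sd.ExprSimConfig(
                n_genes=30, n_planted_trait_genes=0, n_planted_degs=6,
                fold_change=3.0, dispersion=0.25, seed=10_000 + seed,
            )
            b = sd.generate_expression(cfg)
            sub = b["samples"][b["samples"].stage.isin(["ES", "PS"])]
            groups = pd.Series(sub["stage"].to_numpy(), index=sub["sample"].to_numpy())
            called = set(es.call_degs(b["fpkm"], groups)["gene"])
            planted = set(b["truth"].gene[b["truth"].is_deg])
            hits += len(called & planted)
            total += len(planted)
        assert hits / total >= 0.95

    def test_no_fold_change_means_chance_level_calls(self):
        calls = 0
        nulls = 0
        for seed in range(50):
            cfg = sd.ExprSimConfig(
                n_genes=40, n_planted_trait_genes=0, n_planted_degs=10,
                fold_change=0.0, seed=20_000 + seed,
            )
            b = sd.generate_expression(cfg)
            sub = b["samples"][b["samples"].stage.isin(["ES", "PS"])]
            groups = pd.Series(sub["stage"].to_numpy(), index=sub["sample"].to_numpy())
            calls += len(es.call_degs(b["fpkm"], groups))
            nulls += cfg.n_genes
        # the joint p & fold-change threshold makes calls rare under H0
        assert calls / nulls < 0.05


class TestIntersectOrgans:
    def test_disjoint_and_identical(self):
        common, _ = es.intersect_organs({"a": {1, 2}, "b": {3, 4}})
        assert common == set()
        common, _ = es.intersect_organs({"a": {1, 2}, "b": {1, 2}})
        assert common == {1, 2}

    def test_four_way_intersection_and_venn_counts(self):
        sets = {
            "leaf": {"A", "B", "C"},
            "culm": {"B", "C", "D"},
            "rhizome": {"C", "B"},
            "shoot": {"B", "C", "E"},
        }
        common, venn = es.intersect_organs(sets)
        assert common == {"B", "C"}
        assert venn[frozenset(sets)] == 2
        assert venn[frozenset({"leaf"})] == 1  # A only in leaf
        assert sum(venn.values()) == 5  # A..E each counted once

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            es.intersect_organs({"a": {1}})


class TestTraitScreen:
    def test_gene_tracking_trait_is_retained_with_unit_r(self, bundle):
        fpkm, samples, traits = bundle["fpkm"], bundle["samples"], bundle["traits"]
        tn = traits.set_index(["organ", "stage"])["TN"]
        probe = fpkm.iloc[:1].copy()
        probe.index = ["probe"]
        for _, row in samples.iterrows():
            probe.loc["probe", row["sample"]] = tn[(row["organ"], row["stage"])]
        kept, edges = es.trait_screen(probe, samples, traits)
        assert "probe" in kept
        r_tn = edges.query("gene == 'probe' and trait == 'TN'")["r"].iloc[0]
        assert r_tn == pytest.approx(1.0, abs=1e-12)

    def test_require_all_is_monotone_and_consistent_with_edges(self, bundle):
        samples, traits = bundle["samples"], bundle["traits"]
        tn = traits.set_index(["organ", "stage"])["TN"]
        vals = {}
        for _, row in samples.iterrows():
            vals[row["sample"]] = tn[(row["organ"], row["stage"])]
        probe = pd.DataFrame([vals], index=["probe"])
        kept_all, edges = es.trait_screen(probe, samples, traits, require_all=4)
        sig_count = (edges.query("gene == 'probe'")["p"] < 0.05).sum()
        assert ("probe" in kept_all) == (sig_count == 4)
        kept_three = es.trait_screen(probe, samples, traits, require_all=3)[0]
        assert kept_all <= kept_three

    def test_constant_gene_excluded_with_warning(self, bundle):
        probe = bundle["fpkm"].iloc[:1].copy() * 0 + 7.0
        probe.index = ["flat"]
        with pytest.warns(UserWarning, match="constant"):
            kept, edges = es.trait_screen(probe, bundle["samples"], bundle["traits"])
        assert kept == set()
        assert edges.empty

    def test_planted_recall_and_null_fpr(self):
        """Planted trait genes (r≈0.95) are recalled ≥ 0.9; null genes
        pass the all-four-traits filter at ≤ 2α (100 seeded runs here;
        the acceptance suite runs 500)."""
        recalled = planted_n = false_pos = null_n = 0
        for seed in range(100):
            cfg = sd.ExprSimConfig(
                n_genes=40, n_planted_trait_genes=6, n_planted_degs=0,
                seed=30_000 + seed,
            )
            b = sd.generate_expression(cfg)
            kept, _ = es.trait_screen(b["fpkm"], b["samples"], b["traits"])
            planted = set(b["truth"].gene[b["truth"].is_trait_gene])
            nulls = set(b["truth"].gene) - planted
            recalled += len(kept & planted)
            planted_n += len(planted)
            false_pos += len(kept & nulls)
            null_n += len(nulls)
        assert recalled / planted_n >= 0.9
        assert false_pos / null_n <= 2 * 0.05


class TestFpkmFloor:
    def test_boundary_inclusive_and_organ_scoped(self, bundle):
        samples = bundle["samples"]
        cols = list(bundle["fpkm"].columns)
        fpkm = pd.DataFrame(
            [np.zeros(len(cols)), np.full(len(cols), 10.0), np.full(len(cols), 9.99)],
            index=["zero", "at_floor", "below"],
            columns=cols,
        )
        kept = es.fpkm_floor_filter(fpkm, floor=10.0)
        assert kept == {"at_floor"}
        kept_leaf = es.fpkm_floor_filter(fpkm, samples, organ="leaf", floor=10.0)
        assert kept_leaf == {"at_floor"}


class TestIsotopeCorrelation:
    def _n15(self):
        return pd.DataFrame(
            {
                "organ": ["shoot"] * 4,
                "stage": ["ES", "PS", "BS", "LS"],
                "n15_content_g": [0.1, 0.4, 0.5, 0.3],
            }
        )

    def test_expression_equal_to_trajectory_is_starred(self, bundle):
        samples = bundle["samples"]
        traj = {"ES": 0.1, "PS": 0.4, "BS": 0.5, "LS": 0.3}
        vals = {
            row["sample"]: traj[row["stage"]] for _, row in samples.iterrows()
        }
        probe = pd.DataFrame([vals], index=["probe"])
        out = es.isotope_correlation(probe, samples, self._n15())
        row = out.query("gene == 'probe' and organ == 'shoot'").iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["stars"] == "**"

    def test_constant_expression_leaves_blank_cell(self, bundle):
        probe = bundle["fpkm"].iloc[:1] * 0 + 3.0
        probe.index = ["flat"]
        out = es.isotope_correlation(probe, bundle["samples"], self._n15())
        row = out.iloc[0]
        assert np.isnan(row["r"]) and row["stars"] == ""

    def test_permuted_trajectory_star_rate_near_alpha(self):
        """With expression independent of the ¹⁵N trajectory the star
        rate is near the nominal 5% (n=4 pairs, 200 seeded runs)."""
        rng = np.random.default_rng(77)
        cfg = sd.ExprSimConfig(n_genes=1, n_planted_trait_genes=0,
                               n_planted_degs=0, seed=1)
        samples = sd.generate_expression(cfg)["samples"]
        stars = 0
        n15 = self._n15()
        for _ in range(200):
            vals = {
                row["sample"]: rng.uniform(1, 10) for _, row in samples.iterrows()
            }
            probe = pd.DataFrame([vals], index=["g"])
            out = es.isotope_correlation(probe, samples, n15)
            stars += (out["stars"] != "").any()
        assert stars / 200 <= 0.10


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((20.0, 18.0, 20.0, 18.0), 1.0),  # calibrator vs itself
            ((22.0, 24.0, 20.0, 20.0), 4.0),  # ΔΔCt = −2
            ((25.0, 20.0, 24.0, 18.0), 2.0),  # ΔΔCt = −1
        ],
    )
    def test_power_identities(self, args, expected):
        assert es.delta_delta_ct(*args) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            es.delta_delta_ct(np.nan, 20, 20, 18)


class TestFullFunnel:
    def test_nesting_invariants_and_truth_recovery(self, bundle):
        result = es.run_screen(bundle["fpkm"], bundle["samples"], bundle["traits"])
        result.check_nesting()  # raises on violation
        for degs in result.degs_per_organ.values():
            assert result.common_degs <= degs
        assert result.trait_correlated <= result.common_degs
        planted = set(bundle["truth"].gene[bundle["truth"].is_trait_gene])
        assert len(result.trait_correlated & planted) >= 0.8 * len(planted)

    def test_edge_list_round_trips_through_csv(self, bundle, tmp_path):
        result = es.run_screen(bundle["fpkm"], bundle["samples"], bundle["traits"])
        path = tmp_path / "edges.csv"
        result.edges.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, result.edges, check_exact=False, rtol=1e-12)
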