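from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from initnet.compare import (
    PresenceMatrix,
    cluster_networks,
    core_unique_stats,
    group_enrichment,
    overlap_test,
    presence_matrix,
    reporter_metabolites,
)
from initnet.gpr import Gene, Or
from initnet.model_core import MetabolicModel, Metabolite, Reaction
from initnet.synthetic import SyntheticSpec, simulate_network_groups

from conftest import make_model


def exact_hypergeom_tail(k, N, K, n) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact summation."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return total


def simple_models(gene_sets):
    models = []
    for label, genes in gene_sets.items():
        rxns = [
            Reaction(
                id=f"r_{g}",
                stoichiometry={"A": -1.0, "B": 1.0},
                gpr=Gene(g),
            )
            for g in genes
        ]
        models.append(
            MetabolicModel(
                metabolites=[Metabolite(id="A"), Metabolite(id="B")],
                reactions=rxns,
                genes=sorted(genes),
                id=label,
            )
        )
    return models


class TestPresenceMatrix:
    def test_identical_models_identical_columns(self):
        models = simple_models({"n1": {"g1", "g2"}, "n2": {"g1", "g2"}})
        pm = presence_matrix(models, "gene")
        assert (pm.frame["n1"] == pm.frame["n2"]).all()

    def test_disjoint_models_orthogonal(self):
        models = simple_models({"n1": {"g1"}, "n2": {"g2"}})
        pm = presence_matrix(models, "gene")
        assert (pm.frame["n1"] * pm.frame["n2"]).sum() == 0

    def test_column_sums_equal_gene_counts(self):
        gene_sets = {"n1": {"g1", "g2", "g3"}, "n2": {"g2"}, "n3": {"g1", "g4"}}
        pm = presence_matrix(simple_models(gene_sets), "gene")
        for label, genes in gene_sets.items():
            assert pm.frame[label].sum() == len(genes)

    def test_reaction_features(self):
        models = simple_models({"n1": {"g1"}, "n2": {"g2"}})
        pm = presence_matrix(models, "reaction")
        assert set(pm.features) == {"r_g1", "r_g2"}

    def test_duplicate_labels_error(self):
        models = simple_models({"n1": {"g1"}})
        with pytest.raises(ValueError):
            presence_matrix(models * 2, "gene")

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            PresenceMatrix(pd.DataFrame({"n1": [2]}, index=["g1"]), "gene")

    def test_tsv_roundtrip(self, tmp_path):
        pm = presence_matrix(simple_models({"n1": {"g1"}, "n2": {"g1", "g2"}}), "gene")
        pm.to_tsv(tmp_path / "pm.tsv")
        back = PresenceMatrix.from_tsv(tmp_path / "pm.tsv")
        assert back.frame.equals(pm.frame)


class TestGroupEnrichment:
    @staticmethod
    def matrix(rows, labels):
        return PresenceMatrix(
            pd.DataFrame(rows, columns=labels), feature_kind="gene"
        )

    def test_fully_specific_feature_16_vs_24(self):
        # mirrors a 16-vs-24 design: feature in all of group a, none of b
        a = [f"a{i}" for i in range(16)]
        b = [f"b{i}" for i in range(24)]
        rows = pd.DataFrame([[1] * 16 + [0] * 24], index=["f"], columns=a + b)
        pm = PresenceMatrix(rows, "gene")
        res = group_enrichment(pm, a, b)
        expected = 1.0 / comb(40, 16)
        assert res.loc["f", "p_value"] == pytest.approx(expected, rel=1e-12)
        assert bool(res.loc["f", "significant"])

    def test_ubiquitous_feature_p_one(self):
        a, b = ["a0", "a1"], ["b0", "b1"]
        pm = self.matrix({"a0": [1], "a1": [1], "b0": [1], "b1": [1]}, a + b)
        res = group_enrichment(pm, a, b)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_symmetric_balanced_feature(self):
        # equal proportions in equal-size groups: exact enumeration gives >= 0.5
        a, b = ["a0", "a1"], ["b0", "b1"]
        pm = self.matrix({"a0": [1], "a1": [0], "b0": [1], "b1": [0]}, a + b)
        res = group_enrichment(pm, a, b)
        exact = float(exact_hypergeom_tail(1, 4, 2, 2))
        assert res.loc[0, "p_value"] == pytest.approx(exact, abs=1e-12)
        assert res.loc[0, "p_value"] >= 0.5

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exact_summation(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(3, 20)), int(rng.integers(3, 20))
        a = [f"a{i}" for i in range(n_a)]
        b = [f"b{i}" for i in range(n_b)]
        data = rng.integers(0, 2, size=(10, n_a + n_b))
        pm = PresenceMatrix(pd.DataFrame(data, columns=a + b), "gene")
        res = group_enrichment(pm, a, b)
        for f in range(10):
            k_a = int(data[f, :n_a].sum())
            k_b = int(data[f, n_a:].sum())
            exact = float(exact_hypergeom_tail(k_a, n_a + n_b, k_a + k_b, n_a))
            assert res.loc[f, "p_value"] == pytest.approx(exact, abs=1e-10)

    def test_swapping_groups_gives_depletion_direction(self):
        a, b = ["a0", "a1", "a2"], ["b0", "b1", "b2"]
        pm = self.matrix(
            {"a0": [1], "a1": [1], "a2": [1], "b0": [0], "b1": [0], "b2": [0]}, a + b
        )
        enriched = group_enrichment(pm, a, b)
        depleted = group_enrichment(pm, b, a, alternative="less")
        assert enriched.loc[0, "p_value"] == pytest.approx(depleted.loc[0, "p_value"])

    def test_group_validation(self):
        pm = self.matrix({"a0": [1], "b0": [0]}, ["a0", "b0"])
        with pytest.raises(ValueError):
            group_enrichment(pm, ["a0"], ["a0"])
        with pytest.raises(ValueError):
            group_enrichment(pm, [], ["b0"])
        with pytest.raises(ValueError):
            group_enrichment(pm, ["a0"], ["ghost"])


def reporter_template(gene_sets):
    """One metabolite per entry; neighbor genes given explicitly."""
    mets, rxns, genes = [], [], set()
    for i, gs in enumerate(gene_sets):
        gs = list(gs)
        mets.append(Metabolite(id=f"m{i}"))
        gpr = Gene(gs[0]) if len(gs) == 1 else Or(tuple(Gene(g) for g in gs))
        rxns.append(Reaction(id=f"r{i}", stoichiometry={f"m{i}": 1.0}, gpr=gpr))
        genes |= set(gs)
    return MetabolicModel(metabolites=mets, reactions=rxns, genes=sorted(genes))


class TestReporterMetabolites:
    def test_k1_raw_z_equals_gene_z(self):
        from scipy import stats

        template = reporter_template([["g1"], ["g2"]])
        pvals = {"g1": 0.01, "g2": 0.5, "g3": 0.9}
        res = reporter_metabolites(template, pvals, n_null_samples=200, seed=0)
        assert res.loc["m0", "z_raw"] == pytest.approx(stats.norm.isf(0.01))

    def test_top_gene_gives_top_score(self):
        template = reporter_template([["g1", "g2"], ["g3", "g4"]])
        pvals = {"g1": 1e-6, "g2": 1e-6, "g3": 0.6, "g4": 0.7}
        res = reporter_metabolites(template, pvals, n_null_samples=500, seed=0)
        assert res.loc["m0", "z_corrected"] > res.loc["m1", "z_corrected"]

    def test_identical_pvalues_corrected_near_zero(self):
        # all genes share one p: every draw of size k gives the same Z, so the
        # corrected score collapses to ~0 (null sd degenerates to the 1.0 floor)
        template = reporter_template([["g1", "g2"], ["g3"]])
        pvals = {f"g{i}": 0.3 for i in range(1, 5)}
        res = reporter_metabolites(template, pvals, n_null_samples=400, seed=0)
        assert np.allclose(res["z_corrected"], 0.0, atol=1e-9)

    def test_extreme_pvalues_clamped_with_warning(self):
        template = reporter_template([["g1"]])
        with pytest.warns(UserWarning):
            res = reporter_metabolites(template, {"g1": 0.0, "g2": 0.5}, seed=0)
        assert np.isfinite(res.loc["m0", "z_raw"])

    def test_unscored_metabolites_skipped(self):
        template = reporter_template([["g1"], ["g2"]])
        res = reporter_metabolites(template, {"g1": 0.1, "gX": 0.2}, seed=0)
        assert list(res.index) == ["m0"]

    def test_reversible_reactions_count_both_sides(self):
        model = make_model({"r": ({"A": -1.0, "B": 1.0}, True, "g1")})
        res = reporter_metabolites(model, {"g1": 0.05, "g2": 0.5}, seed=0)
        assert set(res.index) == {"A", "B"}


class TestClustering:
    @staticmethod
    def matrix(data, labels):
        return PresenceMatrix(pd.DataFrame(data, columns=labels), "gene")

    def test_identical_columns_merge_first_with_full_support(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, size=30)
        other = rng.integers(0, 2, size=30)
        pm = self.matrix(
            np.column_stack([col, col, other]), ["n1", "n2", "n3"]
        )
        result = cluster_networks(pm, n_bootstrap=50, seed=1)
        assert result.linkage[0, 2] == 0.0
        assert result.supports[frozenset({"n1", "n2"})] == 1.0

    def test_strong_pair_high_support(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 2, size=200)
        near = base.copy()
        near[:20] ^= 1  # 90% shared
        far = rng.integers(0, 2, size=200)
        pm = self.matrix(np.column_stack([base, near, far]), ["n1", "n2", "n3"])
        result = cluster_networks(pm, n_bootstrap=200, seed=2)
        assert result.supports[frozenset({"n1", "n2"})] > 0.95

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 2, size=(50, 4))
        labels = ["n1", "n2", "n3", "n4"]
        pm1 = self.matrix(data, labels)
        perm = [2, 0, 3, 1]
        pm2 = self.matrix(data[:, perm], [labels[i] for i in perm])
        r1 = cluster_networks(pm1, n_bootstrap=10, seed=0)
        r2 = cluster_networks(pm2, n_bootstrap=10, seed=0)
        assert set(map(frozenset, r1.clades())) == set(map(frozenset, r2.clades()))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        pm = self.matrix(rng.integers(0, 2, size=(40, 4)), list("abcd"))
        s1 = cluster_networks(pm, n_bootstrap=100, seed=9).supports
        s2 = cluster_networks(pm, n_bootstrap=100, seed=9).supports
        assert s1 == s2

    def test_newick_output_parses(self):
        import dendropy

        rng = np.random.default_rng(11)
        pm = self.matrix(rng.integers(0, 2, size=(60, 4)), ["w", "x", "y", "z"])
        result = cluster_networks(pm, n_bootstrap=20, seed=0)
        tree = dendropy.Tree.get(data=result.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"w", "x", "y", "z"}

    def test_too_few_networks(self):
        pm = self.matrix(np.array([[1, 0], [0, 1]]), ["a", "b"])
        with pytest.raises(ValueError):
            cluster_networks(pm)

    def test_support_monotone_in_signal(self):
        # sharpening the pair signal cannot reduce bootstrap support
        supports = []
        for flip in (80, 40, 5):
            rng = np.random.default_rng(13)
            base = rng.integers(0, 2, size=200)
            near = base.copy()
            idx = rng.choice(200, size=flip, replace=False)
            near[idx] ^= 1
            far1 = rng.integers(0, 2, size=200)
            far2 = rng.integers(0, 2, size=200)
            pm = self.matrix(
                np.column_stack([base, near, far1, far2]), ["n1", "n2", "n3", "n4"]
            )
            result = cluster_networks(pm, n_bootstrap=150, seed=17)
            supports.append(result.supports.get(frozenset({"n1", "n2"}), 0.0))
        assert supports == sorted(supports)


class TestCoreUnique:
    def test_identical_models(self):
        pm = presence_matrix(simple_models({"n1": {"g1", "g2"}, "n2": {"g1", "g2"}}), "gene")
        stats = core_unique_stats(pm)
        assert stats["n_core"] == 2 and stats["n_unique"] == 0
        assert stats["frac_core"] == 1.0

    def test_disjoint_models(self):
        pm = presence_matrix(simple_models({"n1": {"g1"}, "n2": {"g2"}}), "gene")
        stats = core_unique_stats(pm)
        assert stats["n_core"] == 0 and stats["n_unique"] == 2

    def test_matches_row_sum_recount(self):
        rng = np.random.default_rng(21)
        data = rng.integers(0, 2, size=(50, 6))
        labels = [f"n{i}" for i in range(6)]
        pm = PresenceMatrix(pd.DataFrame(data, columns=labels), "gene")
        stats = core_unique_stats(pm)
        sums = data.sum(axis=1)
        assert stats["n_core"] == int((sums == 6).sum())
        assert stats["n_unique"] == int((sums == 1).sum())


class TestOverlapTest:
    def test_identical_sets_minimal_p(self):
        genes = {f"g{i}" for i in range(5)}
        overlap, p = overlap_test(genes, genes, universe_size=20)
        assert overlap == 5
        assert p == pytest.approx(float(exact_hypergeom_tail(5, 20, 5, 5)), rel=1e-10)
        # that is the smallest achievable p for these sizes
        assert p == pytest.approx(1.0 / comb(20, 5), rel=1e-10)

    def test_disjoint_tiny_reference_huge_universe(self):
        overlap, p = overlap_test({"g1", "g2"}, {"h1"}, universe_size=10_000)
        assert overlap == 0
        assert p == pytest.approx(1.0)

    def test_independence_overlap_near_half(self):
        # 10 of 20 universe genes in the model, 10 in the reference, overlap 5
        model = {f"g{i}" for i in range(10)}
        reference = {f"g{i}" for i in range(5, 15)}
        overlap, p = overlap_test(model, reference, universe_size=20)
        assert overlap == 5
        exact = float(exact_hypergeom_tail(5, 20, 10, 10))
        assert p == pytest.approx(exact, abs=1e-10)
        assert 0.3 < p < 0.9

    def test_validation(self):
        with pytest.raises(ValueError):
            overlap_test({"g1"}, set(), 10)
        with pytest.raises(ValueError):
            overlap_test({"g1", "g2"}, {"g3"}, universe_size=2)


class TestSimulatedGroups:
    def test_fully_differential_feature_flagged(self):
        spec = SyntheticSpec(n_metabolites=15, n_reactions=24, seed=31)
        models, groups, truth = simulate_network_groups(spec, 16, 24, 3)
        a = [l for l, g in groups.items() if g == "a"]
        b = [l for l, g in groups.items() if g == "b"]
        pm = presence_matrix(models, "reaction", labels=[m.id for m in models])
        res = group_enrichment(pm, a, b)
        for rid in truth["reactions"]:
            assert res.loc[rid, "p_value"] == pytest.approx(1.0 / comb(40, 16), rel=1e-9)
            assert bool(res.loc[rid, "significant"])

    def test_null_case_no_flags(self):
        spec = SyntheticSpec(n_metabolites=15, n_reactions=24, seed=37)
        models, groups, truth = simulate_network_groups(spec, 8, 8, 0)
        assert truth["reactions"] == []
        a = [l for l, g in groups.items() if g == "a"]
        b = [l for l, g in groups.items() if g == "b"]
        pm = presence_matrix(models, "reaction", labels=[m.id for m in models])
        res = group_enrichment(pm, a, b)
        assert not res["significant"].any()
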