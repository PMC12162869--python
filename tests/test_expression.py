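import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from sctme import clustering as cl
from sctme import expression as ex
from sctme import synthetic as syn
from conftest import make_adata


def adata_from_values(values):
    """AnnData whose lognorm layer is exactly `values` (cells x genes)."""
    values = np.asarray(values, dtype=float)
    ad = make_adata(np.abs(values) + 1)
    ad.layers["lognorm"] = sp.csr_matrix(values)
    return ad


class TestWilcoxonDE:
    def test_complete_separation_exact_p(self):
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        ad = adata_from_values(vals)
        mask_a = np.array([True] * 3 + [False] * 3)
        t = ex.wilcoxon_de(ad, mask_a, ~mask_a, min_pct=0, logfc_threshold=0)
        assert t["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_filtered_out(self):
        vals = np.tile([[1.0, 2.0]], (6, 1))
        ad = adata_from_values(vals)
        mask_a = np.array([True] * 3 + [False] * 3)
        t = ex.wilcoxon_de(ad, mask_a, ~mask_a)
        assert t.empty  # log2FC = 0 fails the fold-change gate

    def test_swapping_groups_negates_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(0)
        vals = rng.exponential(1.0, size=(30, 8))
        vals[:15] *= 2
        ad = adata_from_values(vals)
        mask = np.array([True] * 15 + [False] * 15)
        t1 = ex.wilcoxon_de(ad, mask, ~mask, min_pct=0, logfc_threshold=0)
        t2 = ex.wilcoxon_de(ad, ~mask, mask, min_pct=0, logfc_threshold=0)
        merged = t1.join(t2, lsuffix="_a", rsuffix="_b")
        assert np.allclose(merged["log2FC_a"], -merged["log2FC_b"])
        assert np.allclose(merged["p_a"], merged["p_b"])

    def test_exact_and_normal_agree_at_ten_vs_ten(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(20):
            vals = rng.normal(5, 1, size=(20, 5))  # continuous: no ties
            ad = adata_from_values(vals)
            mask = np.array([True] * 10 + [False] * 10)
            pe = ex.wilcoxon_de(ad, mask, ~mask, min_pct=0, logfc_threshold=0, method="exact")
            pn = ex.wilcoxon_de(ad, mask, ~mask, min_pct=0, logfc_threshold=0, method="normal")
            worst = max(worst, (pe["p"] - pn.loc[pe.index, "p"]).abs().max())
        assert worst <= 0.01

    def test_overlapping_cell_sets_rejected(self):
        ad = adata_from_values(np.ones((4, 2)))
        mask = np.array([True, True, False, False])
        with pytest.raises(ValueError):
            ex.wilcoxon_de(ad, mask, mask)


class TestFindAllMarkers:
    def test_planted_markers_recovered_per_type(self, planted):
        truth = planted["truth"]
        part = planted["partition"]
        markers = ex.find_all_markers(planted["adata"], part)
        majority = (
            pd.Series(truth.true_type.values).groupby(part.labels).agg(lambda s: s.mode()[0])
        )
        for clid, table in markers.items():
            expected = set(truth.markers[majority.loc[clid]])
            found = set(table[(table["log2FC"] > 0) & (table["p_adj"] < 0.05)].index)
            assert expected <= found

    def test_constant_gene_absent_everywhere(self):
        vals = np.random.default_rng(2).exponential(1, (20, 4))
        vals[:, 0] = 3.0
        vals[:10, 1] += 4
        ad = adata_from_values(vals)
        part = cl.ClusterPartition(0.8, np.repeat([0, 1], 10), 0)
        markers = ex.find_all_markers(ad, part, min_pct=0, logfc_threshold=0.1)
        for t in markers.values():
            assert ad.var_names[0] not in t.index

    def test_single_cluster_rejected(self):
        ad = adata_from_values(np.ones((4, 2)))
        with pytest.raises(ValueError):
            ex.find_all_markers(ad, cl.ClusterPartition(0.8, np.zeros(4, dtype=int), 0))


class TestConsensusSignature:
    def de(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "log2FC", "p_adj"]
        ).set_index("gene").assign(pct_A=1.0, pct_B=1.0, p=lambda d: d["p_adj"])

    def test_consistent_gene_enters_up(self):
        s = ex.derive_consensus_signature(
            self.de([("g1", 0.5, 0.01)]), self.de([("g1", 0.4, 0.01)])
        )
        assert s.up == ["g1"] and s.down == []

    def test_inconsistent_direction_excluded(self):
        with pytest.warns(UserWarning, match="empty"):
            s = ex.derive_consensus_signature(
                self.de([("g1", 0.5, 0.01)]), self.de([("g1", -0.4, 0.01)])
            )
        assert s.up == [] and s.down == []

    def test_subthreshold_gene_excluded(self):
        with pytest.warns(UserWarning, match="empty"):
            s = ex.derive_consensus_signature(
                self.de([("g1", 0.5, 0.01)]), self.de([("g1", 0.2, 0.01)])
            )
        assert s.genes == []

    def test_input_order_is_irrelevant(self):
        a = self.de([("g1", 0.5, 0.01), ("g2", -0.6, 0.001)])
        b = self.de([("g1", 0.4, 0.02), ("g2", -0.3, 0.01)])
        s1 = ex.derive_consensus_signature(a, b)
        s2 = ex.derive_consensus_signature(b, a)
        assert s1.up == s2.up and s1.down == s2.down

    def test_planted_program_recovered_with_correct_signs(self):
        cfg = syn.SynthConfig(
            n_genes=1500,
            n_cells_per_sample=500,
            n_samples_per_group=1,
            group_proportions={"young": [0, 0, 1.0], "adult": [0, 0, 1.0]},
            de_spec=syn.DESpec(cell_type="caf", n_genes=40, log2fc=1.0),
            seed=3,
        )
        from sctme import matrix as mx

        adata, truth = syn.generate_tme_dataset(cfg)
        mx.normalize_log(adata)
        adult = (adata.obs["age_group"] == "adult").to_numpy()
        half = np.random.default_rng(0).random(adata.n_obs) < 0.5
        de1 = ex.wilcoxon_de(adata, adult, ~adult, logfc_threshold=0.25)
        de2 = ex.wilcoxon_de(adata, adult & half, ~adult & half, logfc_threshold=0.25)
        sig = ex.derive_consensus_signature(de1, de2)
        recovered = len(set(sig.up) & set(truth.de_up)) + len(
            set(sig.down) & set(truth.de_down)
        )
        wrong = (set(sig.up) & set(truth.de_down)) | (set(sig.down) & set(truth.de_up))
        assert recovered / 40 >= 0.9
        assert not wrong


class TestModuleScore:
    def test_constant_matrix_scores_exactly_zero(self):
        ad = adata_from_values(np.full((10, 50), 2.0))
        s = ex.module_score(ad, list(ad.var_names[:5]), seed=0)
        assert (s == 0).all()

    def test_background_signature_scores_near_zero(self):
        rng = np.random.default_rng(3)
        ad = adata_from_values(rng.exponential(1.0, size=(400, 300)))
        s = ex.module_score(ad, list(ad.var_names[::10]), seed=1)
        assert abs(s.mean()) < 2 * s.std() / np.sqrt(len(s))

    def test_planted_shift_recovered_within_ten_percent(self):
        # background gene averages span a wide range so the bin-matched
        # controls of the planted genes are background, not each other
        rng = np.random.default_rng(4)
        gene_means = rng.uniform(1, 6, size=500)
        gene_means[:10] = np.linspace(1.5, 5.0, 10)
        base = rng.normal(gene_means, 0.5, size=(500, 500))
        delta = 1.0
        on = np.arange(500) < 250
        base[np.ix_(on, range(10))] += delta
        ad = adata_from_values(base)
        s = ex.module_score(ad, list(ad.var_names[:10]), seed=2)
        diff = s[on].mean() - s[~on].mean()
        assert diff == pytest.approx(delta, rel=0.1)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        ad = adata_from_values(rng.exponential(1.0, size=(50, 100)))
        genes = list(ad.var_names[:8])
        assert ex.module_score(ad, genes, seed=7).equals(ex.module_score(ad, genes, seed=7))

    def test_fully_absent_signature_rejected(self):
        ad = adata_from_values(np.ones((5, 5)))
        with pytest.raises(ValueError):
            ex.module_score(ad, ["nope"])


class TestHypergeometric:
    def test_frozen_exact_value(self):
        # universe 100, set 20, list 10, overlap 5; exact upper tail by
        # fraction arithmetic = 0.025464546427043124
        universe = [f"u{i}" for i in range(100)]
        gene_list = universe[:10]
        gene_set = universe[:5] + universe[50:65]
        r = ex.hypergeometric_enrichment(gene_list, {"s": gene_set}, universe)
        assert r["p"].iloc[0] == pytest.approx(0.025464546427043124, abs=1e-12)

    def test_list_equals_set_equals_universe_gives_p_one(self):
        u = [f"u{i}" for i in range(8)]
        r = ex.hypergeometric_enrichment(u, {"s": u}, u)
        assert r["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_overlap_is_least_significant_for_fixed_margins(self):
        u = [f"u{i}" for i in range(30)]
        p0 = ex.hypergeometric_enrichment(u[:5], {"s": u[10:20]}, u)["p"].iloc[0]
        p2 = ex.hypergeometric_enrichment(u[:5], {"s": u[3:13]}, u)["p"].iloc[0]
        assert p0 >= p2

    def test_matches_brute_force_enumeration_on_small_universes(self):
        rng = np.random.default_rng(6)
        for M, n_set, n_list in [(12, 5, 4), (20, 8, 6), (30, 10, 5)]:
            u = list(range(M))
            s = set(rng.choice(M, n_set, replace=False).tolist())
            lst = set(rng.choice(M, n_list, replace=False).tolist())
            k_obs = len(s & lst)
            hits = total = 0
            for combo in itertools.combinations(u, n_list):
                total += 1
                if len(s & set(combo)) >= k_obs:
                    hits += 1
            r = ex.hypergeometric_enrichment(
                [str(x) for x in lst], {"s": [str(x) for x in s]}, [str(x) for x in u]
            )
            assert r["p"].iloc[0] == pytest.approx(hits / total, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ex.hypergeometric_enrichment(["a"], {"s": ["a"]}, [])


class TestClassifier:
    def fixture(self, seed=3, n_cells=1000):
        # 20 planted signature genes (10 up, 10 down) at log2FC 1; the
        # balanced 1000-cells-per-group design mirrors the human-CAF
        # validation regime
        cfg = syn.SynthConfig(
            n_genes=1200,
            n_cells_per_sample=n_cells,
            n_samples_per_group=1,
            group_proportions={"young": [0, 0, 1.0], "adult": [0, 0, 1.0]},
            de_spec=syn.DESpec(cell_type="caf", n_genes=20, log2fc=1.0),
            seed=seed,
        )
        from sctme import matrix as mx

        adata, truth = syn.generate_tme_dataset(cfg)
        mx.normalize_log(adata)
        return adata, truth

    def test_planted_separation_is_learned(self):
        adata, truth = self.fixture()
        res = ex.train_signature_classifier(
            adata,
            adata.obs["age_group"],
            truth.de_up + truth.de_down,
            n_per_group=1000,
            seed=5,
        )
        assert res.sensitivity >= 0.9 and res.specificity >= 0.9

    def test_fixed_seed_reproduces_split_and_importances(self):
        adata, truth = self.fixture()
        r1 = ex.train_signature_classifier(
            adata, adata.obs["age_group"], truth.de_up[:10], n_per_group=100, seed=11
        )
        r2 = ex.train_signature_classifier(
            adata, adata.obs["age_group"], truth.de_up[:10], n_per_group=100, seed=11
        )
        assert r1.importance.equals(r2.importance)
        assert r1.sensitivity == r2.sensitivity

    def test_too_small_group_rejected(self):
        adata, truth = self.fixture()
        with pytest.raises(ValueError):
            ex.train_signature_classifier(
                adata, adata.obs["age_group"], truth.de_up, n_per_group=10_000
            )


class TestImportanceOverlap:
    def test_identical_vectors_overlap_fully(self):
        imp = pd.Series(np.linspace(1, 0, 20), index=[f"f{i}" for i in range(20)])
        t = ex.importance_overlap_test(imp, imp, [0.5])
        row = t.iloc[0]
        assert row["overlap"] == row["top1"] == row["top2"]
        assert row["fisher_p"] <= 0.05

    def test_random_independent_importances_match_hypergeometric_expectation(self):
        rng = np.random.default_rng(8)
        idx = [f"f{i}" for i in range(100)]
        overlaps = []
        for _ in range(50):
            a = pd.Series(rng.random(100), index=idx)
            b = pd.Series(rng.random(100), index=idx)
            ta = a.sort_values(ascending=False).iloc[19]  # top-20 threshold
            t = ex.importance_overlap_test(a, b, [ta])
            # top1 is 20 by construction; expectation of overlap = 20*top2/100
            overlaps.append(t["overlap"].iloc[0] - 20 * t["top2"].iloc[0] / 100)
        assert np.mean(overlaps) == pytest.approx(0.0, abs=1.0)

    def test_empty_top_sets_give_p_one(self):
        imp = pd.Series([0.1, 0.2], index=["a", "b"])
        t = ex.importance_overlap_test(imp, imp, [5.0])
        assert t["overlap"].iloc[0] == 0 and t["fisher_p"].iloc[0] == 1.0

    def test_mismatched_universes_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError):
            ex.importance_overlap_test(a, b, [0.5])


def test_gmt_roundtrip(tmp_path):
    sigs = {"up": ["a", "b", "c"], "down": ["d"]}
    ex.write_gmt(sigs, tmp_path / "s.gmt")
    assert ex.read_gmt(tmp_path / "s.gmt") == sigs
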