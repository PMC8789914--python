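import numpy as np
import pandas as pd
import pytest

from hyposig.errors import AnalysisError
from hyposig.io import ExpressionMatrix, ProbeMap
from hyposig.labeling import (ClusterLabeling, GseaResult,
                              assign_hypoxia_label, cluster_de,
                              gsea_preranked, kmeans_two_group,
                              preprocess_cohort)

from oracles import gsea_es_bruteforce, kmeans_best_two_partition


def _em(values, **kw):
    idx = [f"g{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=idx, columns=cols), **kw)


class TestPreprocess:
    def test_pseudocount_and_median_centring(self):
        m = _em(np.array([[0.0, 1.0, 3.0]]))
        out = preprocess_cohort(m)
        raw = np.log2(np.array([0.0, 1.0, 3.0]) + 1.0)
        assert np.allclose(out.values.to_numpy()[0], raw - np.median(raw))
        assert out.scale == "log2" and out.centred

    def test_constant_gene_becomes_zero(self):
        out = preprocess_cohort(_em(np.full((1, 5), 7.0)))
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_every_gene_median_exactly_zero(self):
        rng = np.random.default_rng(2)
        out = preprocess_cohort(_em(rng.gamma(2, 50, (30, 21))))
        assert np.allclose(np.median(out.values.to_numpy(), axis=1), 0.0)

    def test_negative_values_rejected(self):
        with pytest.raises(AnalysisError, match="negative"):
            preprocess_cohort(_em(np.array([[-1.0, 2.0]])))


class TestCollapseProbes:
    def test_two_probes_max_mad_wins(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(0, 1, 40)
        vals = pd.DataFrame(
            [profile * 3.0, profile * 1.0],
            index=["gA_p1", "gA_p2"],
            columns=[f"s{j}" for j in range(40)],
        )
        expr = ExpressionMatrix(vals, scale="log2")
        pm = ProbeMap(pd.Series(["gA", "gA"], index=["gA_p1", "gA_p2"]))
        from hyposig.labeling import collapse_probes
        out = collapse_probes(expr, pm)
        assert np.allclose(out.values.loc["gA"], profile * 3.0)

    def test_single_probe_passthrough(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p1"],
                            columns=["s1", "s2", "s3"])
        pm = ProbeMap(pd.Series(["gA"], index=["p1"]))
        from hyposig.labeling import collapse_probes
        out = collapse_probes(ExpressionMatrix(vals, scale="log2"), pm)
        assert list(out.gene_ids) == ["gA"]
        assert np.allclose(out.values.loc["gA"], [1.0, 2.0, 3.0])


class TestKmeans:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (10, 20))
        b = rng.normal(10, 1, (10, 20))
        expr = _em(np.hstack([a, b]), scale="log2", centred=True)
        lab = kmeans_two_group(expr, list(expr.gene_ids), seed=0)
        first_half = lab.assignment.iloc[:20]
        second_half = lab.assignment.iloc[20:]
        assert first_half.nunique() == 1 and second_half.nunique() == 1
        assert first_half.iloc[0] != second_half.iloc[0]

    def test_duplicated_samples_partition_together(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (6, 12))
        x[:, 6:] += 8.0
        dup = np.hstack([x, x])
        expr = _em(dup, scale="log2", centred=True)
        lab = kmeans_two_group(expr, list(expr.gene_ids), seed=1)
        a = lab.assignment.to_numpy()
        assert (a[:12] == a[12:]).all()

    def test_matches_exhaustive_minimum_ss(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (2, 8))  # 2 genes, 8 samples
        expr = _em(x, scale="log2", centred=True)
        lab = kmeans_two_group(expr, list(expr.gene_ids), n_starts=100, seed=2)
        best_mask, best_ss = kmeans_best_two_partition(x.T)
        got = (lab.assignment == lab.assignment.iloc[0]).to_numpy()
        assert (got == best_mask).all() or (got == ~best_mask).all()
        assert lab.inertia == pytest.approx(best_ss, rel=1e-9)

    def test_identical_profiles_rejected(self):
        expr = _em(np.ones((3, 5)), scale="log2", centred=True)
        with pytest.raises(AnalysisError, match="distinct"):
            kmeans_two_group(expr, list(expr.gene_ids), seed=0)


class TestClusterDe:
    @staticmethod
    def _labeled_matrix(delta, n=40, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (50, n))
        x[:10, : n // 2] += delta
        expr = _em(x, scale="log2", centred=True)
        assignment = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2),
                               index=expr.sample_ids)
        return expr, ClusterLabeling(assignment=assignment)

    def test_equal_means_never_selected(self):
        expr, lab = self._labeled_matrix(0.0)
        de = cluster_de(expr, lab)
        assert len(de.up_genes(fc_threshold=1.5)) == 0

    def test_injected_fold_change_selected(self):
        expr, lab = self._labeled_matrix(1.0, n=200, seed=1)
        de = cluster_de(expr, lab)
        up = de.up_genes(fc_threshold=1.5)
        assert set(f"g{i}" for i in range(10)) <= set(up)

    def test_label_swap_flips_direction_only(self):
        expr, lab = self._labeled_matrix(1.0, n=100, seed=2)
        de_a = cluster_de(expr, lab, target="A")
        de_b = cluster_de(expr, lab, target="B")
        assert np.allclose(de_a.table["log2fc"], -de_b.table["log2fc"])
        assert np.allclose(de_a.table["p"], de_b.table["p"])


class TestGseaPreranked:
    def test_hand_running_sum_top_two(self):
        ranking = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                            index=list("abcde"))
        res = gsea_preranked(ranking, ["a", "b"], n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_mirror_set_bottom_two(self):
        ranking = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                            index=list("abcde"))
        res = gsea_preranked(ranking, ["d", "e"], n_perm=50, seed=0)
        assert res.es == pytest.approx(-1.0)

    def test_es_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            n = int(rng.integers(50, 1000))
            metric = pd.Series(rng.normal(0, 2, n),
                               index=[f"g{i}" for i in range(n)])
            gene_set = list(rng.choice(metric.index, size=20, replace=False))
            res = gsea_preranked(metric, gene_set, n_perm=10, seed=trial)
            order = metric.sort_values(ascending=False, kind="stable")
            is_hit = order.index.isin(gene_set)
            assert res.es == pytest.approx(
                gsea_es_bruteforce(order.to_numpy(), is_hit), abs=1e-12)

    def test_set_outside_universe_rejected(self):
        ranking = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(AnalysisError, match="outside"):
            gsea_preranked(ranking, ["zzz"], n_perm=10, seed=0)

    def test_nes_sign_follows_es(self):
        rng = np.random.default_rng(8)
        metric = pd.Series(np.sort(rng.normal(0, 1, 200))[::-1],
                           index=[f"g{i}" for i in range(200)])
        up = gsea_preranked(metric, [f"g{i}" for i in range(15)],
                            n_perm=100, seed=1)
        dn = gsea_preranked(metric, [f"g{i}" for i in range(185, 200)],
                            n_perm=100, seed=1)
        assert up.es > 0 and up.nes > 0
        assert dn.es < 0 and dn.nes < 0


class TestOrientation:
    @staticmethod
    def _lab():
        assignment = pd.Series(["A"] * 5 + ["B"] * 5,
                               index=[f"s{i}" for i in range(10)])
        return ClusterLabeling(assignment=assignment)

    @staticmethod
    def _gsea(nes, p):
        return GseaResult(set_name="HYPOXIA", es=np.sign(nes) * 0.5, nes=nes,
                          p=p, n_permutations=100)

    def test_enriched_cluster_gets_high_label(self):
        lab = assign_hypoxia_label(self._lab(), {
            "A": self._gsea(2.4, 0.004), "B": self._gsea(-2.4, 0.9)})
        assert lab.status == "oriented" and lab.orientation == "A"
        assert (lab.hypoxia_calls().iloc[:5] == "hypoxia-high").all()

    def test_no_enrichment_refused(self):
        lab = assign_hypoxia_label(self._lab(), {
            "A": self._gsea(1.0, 0.4), "B": self._gsea(-1.0, 0.6)})
        assert lab.status == "refused" and lab.orientation is None
        with pytest.raises(AnalysisError, match="refused"):
            lab.hypoxia_calls()

    def test_both_significant_is_inconsistent(self):
        with pytest.raises(AnalysisError, match="both clusters"):
            assign_hypoxia_label(self._lab(), {
                "A": self._gsea(2.0, 0.01), "B": self._gsea(2.0, 0.01)})

    def test_cluster_renaming_invariance(self):
        gsea = {"A": self._gsea(2.4, 0.004), "B": self._gsea(-2.4, 0.9)}
        lab1 = assign_hypoxia_label(self._lab(), gsea)
        renamed = ClusterLabeling(
            assignment=self._lab().assignment.map({"A": "B", "B": "A"}))
        swapped = {"A": gsea["B"], "B": gsea["A"]}
        lab2 = assign_hypoxia_label(renamed, swapped)
        assert (lab1.hypoxia_calls() == lab2.hypoxia_calls()).all()


class TestEndToEndLabelling:
    def test_cluster_recovers_latent_status(self, small_cohort_sim):
        from sklearn.metrics import adjusted_rand_score
        expr, _, truth = small_cohort_sim
        proc = preprocess_cohort(expr)
        lab = kmeans_two_group(proc, truth.program_gene_ids, seed=3)
        ari = adjusted_rand_score(truth.hypoxia_status.to_numpy(),
                                  (lab.assignment == "A").to_numpy())
        assert ari >= 0.8
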