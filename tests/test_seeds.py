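import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from hyposig.errors import AnalysisError, ConfigError
from hyposig.io import CountMatrix
from hyposig.seeds import (DEResult, bh_fdr, de_per_line, normalize_counts,
                           pooled_de_with_batch, select_seed_genes,
                           tmm_norm_factors)
from hyposig.simulate import CellLineSimConfig, simulate_cell_line_counts

from oracles import bh_stepup


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_hand_stepup_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        assert np.allclose(bh_fdr([0.2] * 7), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=200))
    def test_matches_bruteforce_and_statsmodels(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        assert np.allclose(q, bh_stepup(p))
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])


class TestNormalization:
    def test_doubling_a_sample_is_invariant(self, toy_counts):
        logcpm = normalize_counts(toy_counts).values
        doubled = toy_counts.counts.copy()
        doubled["L1_hyp_r1"] *= 2
        logcpm2 = normalize_counts(CountMatrix(doubled, toy_counts.meta)).values
        assert np.allclose(logcpm["L1_hyp_r1"], logcpm2["L1_hyp_r1"],
                           atol=1e-6)

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20],
                               "c": [8, 9, 30]}, index=["g1", "g2", "g3"])
        meta = pd.DataFrame({"line": ["L"] * 3,
                             "condition": ["hypoxia", "hypoxia", "normoxia"],
                             "replicate": [1, 2, 1]}, index=counts.columns)
        f = tmm_norm_factors(CountMatrix(counts, meta).counts)
        assert f["a"] == pytest.approx(f["b"])

    def test_factors_match_direct_formula(self, small_cell_line_sim):
        counts, _ = small_cell_line_sim
        sub = counts.counts.iloc[:, :6]
        f = tmm_norm_factors(sub)

        # independent recomputation with explicit loops
        lib = sub.sum(axis=0).astype(float)
        uq = {}
        for sid in sub.columns:
            col = sub[sid]
            uq[sid] = np.quantile(col[col > 0], 0.75) / lib[sid]
        mean_uq = np.mean(list(uq.values()))
        ref = min(uq, key=lambda sid: abs(uq[sid] - mean_uq))
        raw = {}
        for sid in sub.columns:
            if sid == ref:
                raw[sid] = 1.0
                continue
            ms, ws, as_ = [], [], []
            for g in sub.index:
                o, r = sub.loc[g, sid], sub.loc[g, ref]
                if o > 0 and r > 0:
                    ms.append(np.log2((o / lib[sid]) / (r / lib[ref])))
                    as_.append(0.5 * np.log2((o / lib[sid]) * (r / lib[ref])))
                    ws.append((lib[sid] - o) / (lib[sid] * o)
                              + (lib[ref] - r) / (lib[ref] * r))
            ms, as_, ws = map(np.array, (ms, as_, ws))
            lo_m, hi_m = np.quantile(ms, [0.3, 0.7])
            lo_a, hi_a = np.quantile(as_, [0.05, 0.95])
            keep = (ms >= lo_m) & (ms <= hi_m) & (as_ >= lo_a) & (as_ <= hi_a)
            raw[sid] = 2 ** (np.sum(ms[keep] / ws[keep])
                             / np.sum(1.0 / ws[keep]))
        gm = np.exp(np.mean(np.log(list(raw.values()))))
        for sid in sub.columns:
            assert f[sid] == pytest.approx(raw[sid] / gm, rel=1e-10)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [1, 2]}, index=["g1", "g2"])
        meta = pd.DataFrame({"line": ["L"] * 2,
                             "condition": ["hypoxia", "normoxia"],
                             "replicate": [1, 1]}, index=counts.columns)
        with pytest.raises(AnalysisError, match="all-zero"):
            normalize_counts(CountMatrix(counts, meta))


class TestDePerLine:
    def test_identical_condition_profiles_give_zero_fc(self):
        # two conditions with sample-wise identical count columns
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(200, 2))
        counts = pd.DataFrame(
            np.hstack([base, base]), index=[f"g{i}" for i in range(200)],
            columns=["h1", "h2", "n1", "n2"],
        )
        meta = pd.DataFrame({"line": ["L"] * 4,
                             "condition": ["hypoxia", "hypoxia",
                                           "normoxia", "normoxia"],
                             "replicate": [1, 2, 1, 2]}, index=counts.columns)
        de = de_per_line(CountMatrix(counts, meta), "L")
        assert np.allclose(de.table["log2fc"], 0.0, atol=1e-12)

    def test_missing_condition_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["g1"])
        meta = pd.DataFrame({"line": ["L", "L"],
                             "condition": ["hypoxia", "hypoxia"],
                             "replicate": [1, 2]}, index=counts.columns)
        with pytest.raises(AnalysisError, match="replicates per condition"):
            de_per_line(CountMatrix(counts, meta), "L")

    def test_strong_induction_detected(self):
        # single line, large effect: per-gene detection rate at q<0.05
        hits = trials = 0
        for seed in range(30):
            cfg = CellLineSimConfig(n_genes=2000, n_lines=1, n_reps=3,
                                    n_program_genes=20, dispersion=0.1,
                                    log2fc_low=3.0, log2fc_high=3.0,
                                    line_support_probs={1: 1.0}, seed=seed)
            counts, truth = simulate_cell_line_counts(cfg)
            de = de_per_line(counts, "LINE1")
            q = de.table.loc[truth.program_gene_ids, "q"]
            fc = de.table.loc[truth.program_gene_ids, "direction"]
            hits += int(((q < 0.05) & (fc == "up")).sum())
            trials += len(truth.program_gene_ids)
        assert hits / trials >= 0.9

    def test_sample_order_invariance(self, small_cell_line_sim):
        counts, _ = small_cell_line_sim
        de1 = de_per_line(counts, "LINE1")
        perm = np.random.default_rng(1).permutation(counts.counts.shape[1])
        shuffled = CountMatrix(counts.counts.iloc[:, perm],
                               counts.meta.iloc[perm])
        de2 = de_per_line(shuffled, "LINE1")
        assert np.allclose(de1.table["t"], de2.table["t"])


def _mk_de(table_dict, alpha=0.05):
    tab = pd.DataFrame(table_dict).set_index("gene")
    return DEResult(tab, alpha=alpha)


class TestSelectSeedGenes:
    @staticmethod
    def _line(gene_states):
        # gene_states: gene -> (direction, q)
        return _mk_de({
            "gene": list(gene_states),
            "log2fc": [1.0 if d == "up" else -1.0
                       for d, _ in gene_states.values()],
            "t": [0.0] * len(gene_states),
            "p": [q for _, q in gene_states.values()],
            "q": [q for _, q in gene_states.values()],
            "direction": [d for d, _ in gene_states.values()],
        })

    def test_rule_literal_three_of_four(self):
        lines = {}
        for i in range(4):
            state = ("up", 0.01) if i < 3 else ("up", 0.5)
            lines[f"L{i}"] = self._line({"gA": state})
        assert select_seed_genes(lines, min_lines=3).genes == ["gA"]

    def test_mixed_direction_counts_only_up(self):
        lines = {}
        for i in range(4):
            state = ("up", 0.01) if i < 2 else ("down", 0.01)
            lines[f"L{i}"] = self._line({"gA": state})
        assert select_seed_genes(lines, min_lines=3).genes == []
        assert select_seed_genes(lines, min_lines=2).genes == ["gA"]

    def test_down_in_all_lines_excluded(self):
        lines = {f"L{i}": self._line({"gA": ("down", 0.001)}) for i in range(4)}
        assert select_seed_genes(lines, min_lines=3).genes == []

    def test_min_lines_exceeding_lines_rejected(self):
        lines = {"L0": self._line({"gA": ("up", 0.01)})}
        with pytest.raises(ConfigError):
            select_seed_genes(lines, min_lines=3)

    @given(st.integers(min_value=0, max_value=2**24 - 1))
    def test_monotone_in_min_lines_and_alpha(self, bits):
        # random 4-line up/q patterns over 6 genes
        rng = np.random.default_rng(bits)
        lines = {}
        for i in range(4):
            qs = rng.uniform(0, 0.2, 6)
            dirs = rng.choice(["up", "down"], 6)
            lines[f"L{i}"] = self._line({
                f"g{j}": (dirs[j], qs[j]) for j in range(6)})
        loose = set(select_seed_genes(lines, min_lines=2, alpha=0.1).genes)
        tight_lines = set(select_seed_genes(lines, min_lines=3, alpha=0.1).genes)
        tight_alpha = set(select_seed_genes(lines, min_lines=2, alpha=0.02).genes)
        assert tight_lines <= loose and tight_alpha <= loose


class TestPooledDeWithBatch:
    def test_matches_unadjusted_when_no_line_effects(self):
        cfg = CellLineSimConfig(n_genes=1500, line_effect_sd=0.0,
                                n_program_genes=40, seed=17)
        counts, _ = simulate_cell_line_counts(cfg)
        adj = pooled_de_with_batch(counts)

        # unadjusted pooled moderated test
        from hyposig.seeds import moderated_ttest
        logcpm = normalize_counts(counts).values
        hyp = (counts.meta["condition"] == "hypoxia").to_numpy()
        raw = moderated_ttest(logcpm.to_numpy(), hyp, ~hyp)
        rho = pd.Series(adj.table["p"].to_numpy()).corr(
            pd.Series(raw["p"].to_numpy()), method="spearman")
        assert rho >= 0.99

    def test_single_line_rejected(self):
        cfg = CellLineSimConfig(n_genes=100, n_lines=1,
                                line_support_probs={1: 1.0}, seed=1)
        counts, _ = simulate_cell_line_counts(cfg)
        with pytest.raises(AnalysisError, match="two lines"):
            pooled_de_with_batch(counts)

    def test_all_zero_gene_dropped_and_counted(self, default_cell_line_sim):
        # an all-zero gene has constant log2-CPM (log2 of the pseudo-count)
        # within every line: it must be removed from testing, not tested
        counts, _ = default_cell_line_sim
        frozen = counts.counts.copy()
        frozen.iloc[0] = 0
        de = pooled_de_with_batch(CountMatrix(frozen, counts.meta))
        assert de.n_dropped_constant >= 1
        assert frozen.index[0] not in de.table.index
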