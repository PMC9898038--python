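"""Module scores, cell-cycle phase, stemness, state assignment, markers, ssGSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse
from scipy.stats import mannwhitneyu, spearmanr

from conftest import STATE_POTENCY, leukemia_truth_mask
from lscape import scoring
from lscape.scoring import ScoringError


class TestModuleScore:
    def test_constant_matrix_scores_exactly_zero(self):
        X = sparse.csr_matrix(np.full((10, 40), 2.0))
        gn = [f"g{i}" for i in range(40)]
        s = scoring.module_score(X, gn, gn[:5], n_bins=4, n_ctrl=10, seed=0)
        assert np.allclose(s, 0.0)

    def test_whole_genome_set_scores_near_zero(self):
        rng = np.random.default_rng(0)
        X = sparse.csr_matrix(rng.random((50, 200)))
        gn = [f"g{i}" for i in range(200)]
        s = scoring.module_score(X, gn, gn, n_bins=10, n_ctrl=50, seed=0)
        assert np.abs(s).max() < 0.05

    def test_missing_set_raises_with_gene_names(self):
        X = sparse.csr_matrix(np.ones((3, 4)))
        with pytest.raises(ScoringError, match="ZZZ"):
            scoring.module_score(X, ["a", "b", "c", "d"], ["ZZZ"], seed=0)

    def test_planted_cycling_program_separates_cells(self, small_analysis):
        """Proliferation module score discriminates cycling (S/G2M) from G1
        truth cells with AUC >= 0.9."""
        scores = small_analysis["scores"]
        phase = small_analysis["adata"].obs["true_phase"]
        on = scores.loc[phase != "G1", "proliferation"]
        off = scores.loc[phase == "G1", "proliferation"]
        u = mannwhitneyu(on, off).statistic
        auc = u / (len(on) * len(off))
        assert auc >= 0.9


class TestCyclePhase:
    @pytest.mark.parametrize("s,g,expected", [
        (-0.2, -0.1, "G1"), (0.5, 0.1, "S"), (0.1, 0.5, "G2M"),
        (0.0, 0.0, "G1"), (-0.1, 0.2, "G2M"),
    ])
    def test_rule(self, s, g, expected):
        assert scoring.cycle_phase(np.array([s]), np.array([g]))[0] == expected

    def test_planted_s_cells_called_s(self, small_analysis):
        scores = small_analysis["scores"]
        truth = small_analysis["adata"].obs["true_phase"]
        s_cells = truth == "S"
        assert (scores.loc[s_cells, "phase"] == "S").mean() >= 0.9


class TestStemness:
    def test_orders_planted_differentiation_ranks(self, small_analysis):
        ts, mask = leukemia_truth_mask(small_analysis)
        cells = ts.index[mask]
        rho = spearmanr(small_analysis["scores"].loc[cells, "stemness"],
                        ts.loc[cells].map(STATE_POTENCY))[0]
        assert rho >= 0.7

    def test_identical_cells_all_map_to_half(self):
        X = sparse.csr_matrix(np.tile([1.0, 0, 2, 0, 3], (6, 1)))
        adj = sparse.csr_matrix(np.ones((6, 6)) - np.eye(6))
        s = scoring.stemness_score(X, adj)
        assert np.allclose(s, 0.5)

    def test_zero_alpha_smoothing_is_identity_on_ranks(self):
        rng = np.random.default_rng(0)
        X = sparse.csr_matrix(rng.poisson(1.0, (40, 60)).astype(float))
        adj = sparse.csr_matrix((np.ones(80), (rng.integers(0, 40, 80),
                                               rng.integers(0, 40, 80))), shape=(40, 40))
        s0 = scoring.stemness_score(X, adj, smooth_alpha=0.0)
        s_ref = scoring.stemness_score(X, adj, smooth_steps=0)
        assert np.allclose(s0, s_ref)


class TestAssignStates:
    def _scores(self, rows):
        cols = ["lineage:stem", "lineage:GMP", "lineage:granulocyte",
                "lineage:promono", "lineage:mono", "proliferation", "phase"]
        return pd.DataFrame(rows, columns=cols,
                            index=[f"c{i}" for i in range(len(rows))])

    def _leuk(self, n):
        return pd.Series(["leukemia-like"] * n, index=[f"c{i}" for i in range(n)])

    def test_rule_table(self):
        sc = self._scores([
            [1.0, 0, 0, 0, 0, -0.3, "G1"],   # stem + quiescent -> QSC
            [1.0, 0, 0, 0, 0, 0.4, "S"],     # stem + proliferating -> PSP
            [0, 1.0, 0, 0, 0, 0.1, "G1"],    # GMP lineage
            [0, 0, 1.0, 0, 0, 0.5, "S"],     # granulocyte cycling -> PG
            [0, 0, 1.0, 0, 0, -0.2, "G1"],   # granulocyte G1 -> GMP fallback
            [0, 0, 0, 1.0, 0, 0.0, "G1"],    # promono
            [0, 0, 0, 0, 1.0, 0.0, "G1"],    # mono
        ])
        out = scoring.assign_states(sc, self._leuk(7))
        assert list(out.states) == ["QSC", "PSP", "GMP", "PG", "GMP", "promono", "mono"]

    def test_lineage_ties_break_in_fixed_order(self):
        sc = self._scores([[0.5, 0.5, 0.5, 0.5, 0.5, -1.0, "G1"]])
        assert scoring.assign_states(sc, self._leuk(1)).states.iloc[0] == "QSC"

    def test_deterministic_pure_function(self, small_analysis):
        a1 = scoring.assign_states(small_analysis["scores"], small_analysis["mal"].per_cell)
        a2 = scoring.assign_states(small_analysis["scores"], small_analysis["mal"].per_cell)
        assert a1.states.equals(a2.states)

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=8, unique=True))
    @settings(deadline=None, max_examples=25)
    def test_raising_tau_never_moves_qsc_to_psp(self, taus):
        rng = np.random.default_rng(0)
        n = 30
        sc = self._scores([[1.0, 0, 0, 0, 0, p, "G1"] for p in rng.normal(0, 0.5, n)])
        leuk = self._leuk(n)
        taus = sorted(taus)
        prev_qsc = set()
        for tau in taus:
            out = scoring.assign_states(sc, leuk, tau=tau)
            qsc = set(out.states.index[out.states == "QSC"])
            assert prev_qsc <= qsc
            prev_qsc = qsc

    def test_no_leukemia_cells_is_an_error(self):
        sc = self._scores([[1.0, 0, 0, 0, 0, 0.0, "G1"]])
        empty = pd.Series(["normal-like"], index=["c0"])
        with pytest.raises(ScoringError):
            scoring.assign_states(sc, empty)


class TestSurfaceMarkers:
    def test_planted_qsc_surface_markers_recovered(self, small_analysis):
        """CD52, LGALS1 and CD47 are planted in the QSC program and flagged as
        surface genes; all three must appear in the QSC marker table."""
        ts, mask = leukemia_truth_mask(small_analysis)
        adata = small_analysis["adata"]
        cells = ts.index[mask]
        m = adata.obs_names.isin(cells)
        tab = scoring.surface_markers(
            small_analysis["norm"][m], adata.var_names.to_numpy(),
            small_analysis["assign"].states.loc[adata.obs_names[m]],
            adata.uns["surface_genes"] if "surface_genes" in adata.uns
            else small_analysis["cfg"].gene_names)
        qsc = set(tab[tab["state"] == "QSC"]["gene"])
        assert {"CD52", "LGALS1", "CD47"} <= qsc

    def test_constant_gene_never_reported(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, (60, 10)).astype(float)
        X[:, 0] = 3.0
        states = pd.Series(["A"] * 30 + ["B"] * 30)
        tab = scoring.surface_markers(sparse.csr_matrix(X),
                                      [f"g{i}" for i in range(10)], states,
                                      [f"g{i}" for i in range(10)])
        assert "g0" not in set(tab["gene"])

    def test_invariant_to_cell_and_gene_order(self, small_analysis):
        rng = np.random.default_rng(1)
        dense = rng.poisson(1.5, (80, 12)).astype(float)
        dense[:40, 2] += 2.0
        X = sparse.csr_matrix(dense)
        gn = np.array([f"g{i}" for i in range(12)])
        states = pd.Series(["A"] * 40 + ["B"] * 40)
        base = scoring.surface_markers(X, gn, states, gn)
        perm = rng.permutation(80)
        t_cells = scoring.surface_markers(X[perm], gn, states.iloc[perm].reset_index(drop=True), gn)
        gperm = rng.permutation(12)
        t_genes = scoring.surface_markers(X[:, gperm], gn[gperm], states, gn)
        key = lambda t: sorted(map(tuple, t[["state", "gene"]].to_numpy()))
        assert key(base) == key(t_cells) == key(t_genes)

    def test_permuted_labels_yield_almost_no_hits(self, small_analysis):
        ts, mask = leukemia_truth_mask(small_analysis)
        adata = small_analysis["adata"]
        cells = ts.index[mask]
        m = adata.obs_names.isin(cells)
        sub = small_analysis["norm"][m]
        states = small_analysis["assign"].states.loc[adata.obs_names[m]].reset_index(drop=True)
        surface = adata.uns["surface_genes"]
        rng = np.random.default_rng(0)
        n_hits = []
        for _ in range(100):
            perm = pd.Series(rng.permutation(states.to_numpy()))
            tab = scoring.surface_markers(sub, adata.var_names.to_numpy(), perm, surface)
            n_hits.append(len(tab))
        assert np.mean(np.asarray(n_hits) <= 1) >= 0.95


class TestSsgsea:
    def test_top_ranked_set_is_maximal_among_same_size_sets(self):
        rng = np.random.default_rng(0)
        x = rng.random((1, 100))
        gn = np.array([f"g{i}" for i in range(100)])
        top = gn[np.argsort(-x[0])[:10]]
        s_top = scoring.ssgsea_score(x, gn, top)[0]
        for _ in range(50):
            rand = rng.choice(gn, 10, replace=False)
            assert s_top >= scoring.ssgsea_score(x, gn, rand)[0]

    def test_random_sets_center_on_zero(self):
        rng = np.random.default_rng(1)
        gn = np.array([f"g{i}" for i in range(300)])
        vals = []
        for i in range(1000):
            x = rng.random((1, 300))
            s = scoring.ssgsea_score(x, gn, rng.choice(gn, 25, replace=False))
            vals.append(s[0])
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals))

    def test_planted_stem_signature_enriched_in_stem_states(self, small_analysis):
        adata = small_analysis["adata"]
        ts, mask = leukemia_truth_mask(small_analysis)
        stem_set = adata.uns["gene_sets"]["lineage:stem"]
        cells_stem = ts.index[mask & ts.isin(["QSC", "PSP"])]
        cells_mono = ts.index[mask & (ts == "mono")]
        sub = lambda cells: small_analysis["norm"][adata.obs_names.isin(cells)]
        s_stem = scoring.ssgsea_score(sub(cells_stem)[:100], adata.var_names.to_numpy(), stem_set)
        s_mono = scoring.ssgsea_score(sub(cells_mono)[:100], adata.var_names.to_numpy(), stem_set)
        assert mannwhitneyu(s_stem, s_mono, alternative="greater").pvalue < 0.01

    def test_empty_intersection_rejected(self):
        with pytest.raises(ScoringError):
            scoring.ssgsea_score(np.ones((1, 5)), [f"g{i}" for i in range(5)], ["nope"])
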