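"""Label transfer, composition shifts, per-state DE and the reprogramming index."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from lscape import longitudinal, preprocess, synthetic
from lscape.longitudinal import LongitudinalError


@pytest.fixture(scope="module")
def reference_world(small_cohort):
    adata, truth = small_cohort
    leuk = adata.obs["true_malignant"].to_numpy()
    sub = adata[leuk].copy()
    rng = np.random.default_rng(0)
    hold = rng.random(sub.n_obs) < 0.2
    ref = sub[~hold].copy()
    qry = sub[hold].copy()
    norm = preprocess.normalize_log(ref)
    emb = preprocess.reduce_and_graph(ref, norm, n_hvg=500, d=20, k=15, seed=0)
    return {"ref": ref, "qry": qry, "emb": emb}


class TestTransferLabels:
    def test_self_transfer_is_perfect(self, reference_world):
        ref, emb = reference_world["ref"], reference_world["emb"]
        res = longitudinal.transfer_labels(ref.obs["true_state"].astype(str),
                                           ref.obs_names.to_numpy(), emb, ref.copy())
        assert (res.labels == ref.obs["true_state"].astype(str)).all()
        assert ((res.confidence > 0) & (res.confidence <= 1)).all()

    def test_holdout_accuracy_at_least_ninety_percent(self, reference_world):
        ref, qry, emb = (reference_world["ref"], reference_world["qry"],
                         reference_world["emb"])
        res = longitudinal.transfer_labels(ref.obs["true_state"].astype(str),
                                           ref.obs_names.to_numpy(), emb, qry)
        acc = (res.labels == qry.obs["true_state"].astype(str)).mean()
        assert acc >= 0.90

    def test_k_one_equals_nearest_neighbor(self, reference_world):
        ref, qry, emb = (reference_world["ref"], reference_world["qry"],
                         reference_world["emb"])
        labels = ref.obs["true_state"].astype(str)
        res = longitudinal.transfer_labels(labels, ref.obs_names.to_numpy(), emb, qry, k=1)
        qn = preprocess.normalize_log(qry)
        q_pcs = emb.project(qn, qry.var_names.to_numpy())
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=1).fit(emb.pcs)
        _, idx = nn.kneighbors(q_pcs)
        expected = labels.iloc[idx.ravel()].to_numpy()
        assert (res.labels.to_numpy() == expected).all()

    def test_query_cell_order_invariance(self, reference_world):
        ref, qry, emb = (reference_world["ref"], reference_world["qry"],
                         reference_world["emb"])
        labels = ref.obs["true_state"].astype(str)
        res1 = longitudinal.transfer_labels(labels, ref.obs_names.to_numpy(), emb, qry)
        rng = np.random.default_rng(1)
        perm = rng.permutation(qry.n_obs)
        res2 = longitudinal.transfer_labels(labels, ref.obs_names.to_numpy(), emb,
                                            qry[perm].copy())
        assert res1.labels.sort_index().equals(res2.labels.sort_index())

    def test_insufficient_shared_genes_rejected(self, reference_world):
        ref, qry, emb = (reference_world["ref"], reference_world["qry"],
                         reference_world["emb"])
        tiny = qry[:, :50].copy()
        with pytest.raises(LongitudinalError, match="shares only"):
            longitudinal.transfer_labels(ref.obs["true_state"].astype(str),
                                         ref.obs_names.to_numpy(), emb, tiny)


class TestCompositionShift:
    def test_identical_compositions_zero_delta(self):
        s = pd.Series(["QSC"] * 5 + ["mono"] * 5)
        table = longitudinal.composition_shift(s, s.copy())
        assert np.allclose(table.proportions["delta"], 0.0)
        assert table.proportions["pre"].sum() == pytest.approx(1.0)
        assert table.proportions["post"].sum() == pytest.approx(1.0)

    def test_planted_qsc_increase_recovered(self, small_cfg):
        """The refractory-patient pattern (QSC 5.5% -> 10.7%) survives label
        transfer within two percentage points at 2,000 cells per timepoint."""
        pre, post, truth = synthetic.simulate_longitudinal(small_cfg, 0.0,
                                                           cells_per_timepoint=2000)
        norm = preprocess.normalize_log(pre)
        emb = preprocess.reduce_and_graph(pre, norm, n_hvg=500, d=20, k=15, seed=0)
        res = longitudinal.transfer_labels(pre.obs["true_state"].astype(str),
                                           pre.obs_names.to_numpy(), emb, post)
        table = longitudinal.composition_shift(pre.obs["true_state"].astype(str),
                                               res.labels)
        for stt in ("QSC", "PSP"):
            assert table.proportions.loc[stt, "pre"] == pytest.approx(
                truth.sample_composition.loc["LP1_pre", stt], abs=0.02)
            assert table.proportions.loc[stt, "post"] == pytest.approx(
                truth.sample_composition.loc["LP1_post", stt], abs=0.02)

    def test_empty_timepoint_rejected(self):
        s = pd.Series(["QSC"])
        with pytest.raises(LongitudinalError):
            longitudinal.composition_shift(s, s.iloc[:0])


class TestStateDE:
    def _pair(self, shift_genes=0, n=80, n_genes=120, factor=2.0, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.5, 3.0, n_genes)
        pre = rng.poisson(base, (n, n_genes)).astype(float)
        post_mean = base.copy()
        post_mean[:shift_genes] *= factor
        post = rng.poisson(post_mean, (n, n_genes)).astype(float)
        pre = np.log1p(pre)
        post = np.log1p(post)
        gn = np.array([f"g{i}" for i in range(n_genes)])
        return sparse.csr_matrix(pre), sparse.csr_matrix(post), gn

    def test_null_populations_give_no_hits(self):
        hits = []
        for seed in range(10):
            pre, post, gn = self._pair(0, seed=seed)
            tab = longitudinal.state_de(pre, post, gn)
            hits.append(len(tab))
        assert np.mean(np.asarray(hits) == 0) >= 0.9

    def test_planted_twofold_shift_recovered(self):
        pre, post, gn = self._pair(20, n=150, factor=2.0, seed=1)
        tab = longitudinal.state_de(pre, post, gn)
        planted = {f"g{i}" for i in range(20)}
        found = set(tab.index)
        assert len(found & planted) >= 18
        assert len(found - planted) <= 2

    def test_gene_order_invariance(self):
        pre, post, gn = self._pair(10, seed=2)
        tab1 = longitudinal.state_de(pre, post, gn)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(gn))
        tab2 = longitudinal.state_de(pre[:, perm], post[:, perm], gn[perm])
        assert sorted(tab1.index) == sorted(tab2.index)

    def test_insufficient_cells_named_in_error(self):
        pre, post, gn = self._pair(0)
        with pytest.raises(LongitudinalError, match="QSC"):
            longitudinal.state_de(pre[:2], post, gn, state="QSC")


class TestReprogrammingIndex:
    def _groups(self, seed=0, n=60, n_genes=50, sep=2.0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(1.0, 3.0, n_genes)
        qsc_mean = base.copy()
        qsc_mean[:10] += sep
        q = np.log1p(rng.poisson(qsc_mean, (n, n_genes)).astype(float))
        p = np.log1p(rng.poisson(base, (n, n_genes)).astype(float))
        gn = np.array([f"g{i}" for i in range(n_genes)])
        return q, p, gn

    def test_unchanged_psp_scores_zero(self):
        q, p, gn = self._groups()
        rp = longitudinal.reprogramming_index(q, p, p, gn, [f"g{i}" for i in range(20)])
        assert rp.r == pytest.approx(0.0, abs=1e-12)

    def test_fully_qsc_like_scores_one(self):
        q, p, gn = self._groups()
        rp = longitudinal.reprogramming_index(q, p, q, gn, [f"g{i}" for i in range(20)])
        assert rp.r == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_non_de_genes_with_equal_means(self):
        q, p, gn = self._groups()
        de = [f"g{i}" for i in range(15)]
        rp1 = longitudinal.reprogramming_index(q, p, p + 0.3, gn, de)
        # append constant genes, identical in every group
        pad = np.full((q.shape[0], 5), 1.7)
        q2 = np.hstack([q, pad])
        p2 = np.hstack([p, pad])
        gn2 = np.concatenate([gn, [f"pad{i}" for i in range(5)]])
        rp2 = longitudinal.reprogramming_index(q2, p2, np.hstack([p + 0.3, pad]),
                                               gn2, de + [f"pad{i}" for i in range(5)])
        assert rp2.r == pytest.approx(rp1.r, abs=1e-9)

    def test_coincident_centroids_rejected(self):
        q, p, gn = self._groups()
        with pytest.raises(LongitudinalError, match="coincide"):
            longitudinal.reprogramming_index(p, p, q, gn, [f"g{i}" for i in range(10)])

    def test_monotone_in_planted_lambda(self, small_cfg):
        rs = []
        for lam in (0.0, 0.5, 1.0):
            pre, post, _ = synthetic.simulate_longitudinal(small_cfg, lam,
                                                           cells_per_timepoint=1200)
            pre_n = preprocess.normalize_log(pre)
            post_n = preprocess.normalize_log(post)
            pl = pre.obs["true_state"]
            gn = pre.var_names.to_numpy()
            axis = longitudinal.state_de(pre_n[(pl == "PSP").to_numpy()],
                                         pre_n[(pl == "QSC").to_numpy()], gn)
            rp = longitudinal.reprogramming_index(
                pre_n[(pl == "QSC").to_numpy()], pre_n[(pl == "PSP").to_numpy()],
                post_n[(post.obs["true_state"] == "PSP").to_numpy()],
                gn, list(axis.index))
            rs.append(rp.r)
        assert rs[0] < rs[1] < rs[2]
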