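"""NMF extraction, similarity analysis, refitting, and bootstrap intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lesionscape import synthetic as syn
from lesionscape.channels import ChannelMatrix, SBS96_LABELS
from lesionscape.signatures import (
    ExposureMatrix,
    SignatureSet,
    bootstrap_exposures,
    cosine_similarity,
    dendrogram_to_newick,
    hier_cluster,
    match_signatures,
    nmf_extract,
    profile_mds,
    rank_survey,
    refit_exposures,
    _kl_divergence,
)


def _matrix(counts: np.ndarray) -> ChannelMatrix:
    df = pd.DataFrame(counts, columns=SBS96_LABELS,
                      index=[f"S{i}" for i in range(counts.shape[0])])
    return ChannelMatrix(scheme="SBS96", counts=df.astype(int))


@pytest.fixture(scope="module")
def truth_sigs():
    return syn.default_signatures()


class TestNmfExtract:
    def test_rank1_exact_recovery(self, truth_sigs):
        sig = truth_sigs.iloc[:, [0]].to_numpy().ravel()
        expo = np.array([2000.0, 5000.0, 800.0, 12000.0])
        counts = np.rint(np.outer(expo, sig)).astype(int)
        S, E, obj = nmf_extract(_matrix(counts), K=1, n_runs=3, seed=1)
        assert cosine_similarity(S.profiles.iloc[:, 0], sig) >= 0.999
        assert np.corrcoef(E.exposures.iloc[:, 0], expo)[0, 1] >= 0.999

    def test_two_signature_recovery(self, truth_sigs):
        rng = np.random.default_rng(5)
        f = np.concatenate([rng.uniform(0.8, 0.95, 5), rng.uniform(0.0, 0.3, 10)])
        expo = np.column_stack([f, 1 - f])
        mat = syn.make_channel_matrix(truth_sigs, expo, 20_000, seed=6)
        S, E, obj = nmf_extract(mat, K=2, n_runs=8, seed=7)
        _, sims = match_signatures(S.profiles, truth_sigs)
        assert (sims >= 0.99).all()

    def test_objective_equals_recomputed_kl(self, truth_sigs):
        rng = np.random.default_rng(8)
        expo = rng.dirichlet((2, 2), 6)
        mat = syn.make_channel_matrix(truth_sigs, expo, 5_000, seed=9)
        S, E, obj = nmf_extract(mat, K=2, n_runs=3, seed=10)
        V = mat.counts.to_numpy(float).T
        WH = S.profiles.to_numpy() @ E.exposures.to_numpy().T
        assert obj == pytest.approx(_kl_divergence(V, WH), rel=1e-9)

    def test_reconstruction_unchanged_by_normalization(self, truth_sigs):
        # columns sum to one, exposures carry the scale: S @ x reproduces the
        # unnormalized factorization
        rng = np.random.default_rng(11)
        expo = rng.dirichlet((2, 2), 6)
        mat = syn.make_channel_matrix(truth_sigs, expo, 5_000, seed=12)
        S, E, _ = nmf_extract(mat, K=2, n_runs=3, seed=13)
        assert np.allclose(S.profiles.sum(axis=0), 1.0, atol=1e-9)
        # exposures approximately recover sample totals
        assert E.exposures.sum(axis=1).to_numpy() == pytest.approx(
            mat.counts.sum(axis=1).to_numpy(), rel=0.05
        )

    def test_seed_determinism(self, truth_sigs):
        mat = syn.make_channel_matrix(
            truth_sigs, np.array([[0.7, 0.3], [0.2, 0.8]]), 3_000, seed=14
        )
        S1, E1, o1 = nmf_extract(mat, K=2, n_runs=4, seed=15)
        S2, E2, o2 = nmf_extract(mat, K=2, n_runs=4, seed=15)
        assert o1 == o2
        pd.testing.assert_frame_equal(S1.profiles, S2.profiles)

    def test_k_too_large(self, truth_sigs):
        mat = syn.make_channel_matrix(truth_sigs, np.array([[0.5, 0.5]]), 1_000, seed=2)
        with pytest.raises(ValueError):
            nmf_extract(mat, K=5, n_runs=2, seed=3)

    def test_sklearn_agreement(self, truth_sigs):
        """Independent cross-check: sklearn's KL multiplicative-update NMF
        reaches the same objective region on the same matrix."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(16)
        expo = rng.dirichlet((2, 2), 8)
        mat = syn.make_channel_matrix(truth_sigs, expo, 10_000, seed=17)
        _, _, obj = nmf_extract(mat, K=2, n_runs=5, seed=18)
        V = mat.counts.to_numpy(float).T
        m = NMF(n_components=2, solver="mu", beta_loss="kullback-leibler",
                init="random", random_state=0, max_iter=1000)
        W = m.fit_transform(V)
        assert obj == pytest.approx(m.reconstruction_err_**2 / 2, rel=0.2) or \
            abs(obj - _kl_divergence(V, W @ m.components_)) / max(obj, 1.0) < 0.05


class TestRankSurvey:
    def test_monotone_rss_and_inflection(self, truth_sigs):
        s3 = truth_sigs.copy()
        v = pd.Series(0.0, index=truth_sigs.index)
        for lab in v.index:
            if lab[2:5] in ("T>A", "T>G"):
                v[lab] = 2.0 if lab[0] in "AG" else 1.0
        s3["third"] = v / v.sum()
        rng = np.random.default_rng(20)
        expo = rng.dirichlet((2, 2, 2), 12)
        mat = syn.make_channel_matrix(s3, expo, 15_000, seed=21)
        rd = rank_survey(mat, range(1, 5), n_runs=5, seed=22)
        rss = rd.table["rss"].to_numpy()
        assert (np.diff(rss) <= 1e-6).all()  # non-increasing in K
        # inflection at the true rank: drop to K=3 dwarfs the drop after
        drop_to_true = rss[1] - rss[2]
        drop_after = rss[2] - rss[3]
        assert drop_to_true > 5 * max(drop_after, 1e-9)

    def test_single_k(self, truth_sigs):
        mat = syn.make_channel_matrix(truth_sigs, np.array([[0.6, 0.4]]), 2_000, seed=23)
        rd = rank_survey(mat, [1], n_runs=3, seed=24)
        assert list(rd.table.index) == [1]


class TestCosine:
    def test_identical_and_disjoint(self):
        p = np.array([0.5, 0.5, 0.0])
        q = np.array([0.0, 0.0, 1.0])
        assert cosine_similarity(p, p) == pytest.approx(1.0)
        assert cosine_similarity(p, q) == pytest.approx(0.0)

    def test_hand_computation(self):
        p = np.array([3.0, 4.0, 0.0])
        q = np.array([0.0, 4.0, 3.0])
        assert cosine_similarity(p, q) == pytest.approx(16.0 / 25.0)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestMds:
    def test_group_separation(self, truth_sigs):
        rng = np.random.default_rng(30)
        A = truth_sigs.iloc[:, 0].to_numpy()
        B = truth_sigs.iloc[:, 1].to_numpy()
        profiles = np.array(
            [A + rng.uniform(0, 1e-3, 96) for _ in range(4)]
            + [B + rng.uniform(0, 1e-3, 96) for _ in range(4)]
        )
        xy = profile_mds(profiles)
        d = lambda i, j: np.linalg.norm(xy[i] - xy[j])
        within = max(d(0, 1), d(4, 5))
        between = min(d(i, j) for i in range(4) for j in range(4, 8))
        assert between > 5 * within

    def test_identical_profiles_collapse(self):
        with pytest.warns(UserWarning):
            xy = profile_mds(np.ones((4, 10)))
        assert np.allclose(xy, 0.0)

    def test_order_invariance_up_to_sign(self, truth_sigs):
        rng = np.random.default_rng(31)
        profiles = rng.dirichlet(np.ones(96), 6)
        xy1 = profile_mds(profiles)
        perm = rng.permutation(6)
        xy2 = profile_mds(profiles[perm])
        d1 = np.linalg.norm(xy1[:, None] - xy1[None, :], axis=-1)
        d2 = np.linalg.norm(xy2[:, None] - xy2[None, :], axis=-1)
        assert np.allclose(d1[np.ix_(perm, perm)], d2, atol=1e-8)


class TestHierCluster:
    def test_planted_two_clusters(self, truth_sigs):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(32)
        A = truth_sigs.iloc[:, 0].to_numpy()
        B = truth_sigs.iloc[:, 1].to_numpy()
        profiles = np.array(
            [A + rng.uniform(0, 1e-3, 96) for _ in range(3)]
            + [B + rng.uniform(0, 1e-3, 96) for _ in range(3)]
        )
        names = [f"p{i}" for i in range(6)]
        Z = hier_cluster(profiles, names)
        parts = fcluster(Z, 2, criterion="maxclust")
        assert len(set(parts[:3])) == 1 and len(set(parts[3:])) == 1
        assert parts[0] != parts[3]

    def test_identical_reference_joins_at_zero(self, truth_sigs):
        A = truth_sigs.iloc[:, 0].to_numpy()
        B = truth_sigs.iloc[:, 1].to_numpy()
        Z = hier_cluster(np.array([A, A, B]), ["a", "a_ref", "b"])
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_newick_export(self, truth_sigs):
        A = truth_sigs.iloc[:, 0].to_numpy()
        B = truth_sigs.iloc[:, 1].to_numpy()
        Z = hier_cluster(np.array([A, B]), ["a", "b"])
        nwk = dendrogram_to_newick(Z, ["a", "b"])
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "a:" in nwk and "b:" in nwk


class TestRefit:
    def test_exact_mixture_recovered(self, truth_sigs):
        S = truth_sigs.to_numpy()
        x = np.array([7000.0, 3000.0])
        m = S @ x
        mat = _matrix(np.rint(m)[None, :])
        sigs = SignatureSet(scheme="SBS96", profiles=truth_sigs)
        expo, resid = refit_exposures(mat, sigs)
        assert expo.exposures.iloc[0].to_numpy() == pytest.approx(x, rel=0.02)
        assert resid.iloc[0] < np.linalg.norm(m) * 0.02

    def test_zero_sample(self, truth_sigs):
        mat = _matrix(np.zeros((1, 96)))
        sigs = SignatureSet(scheme="SBS96", profiles=truth_sigs)
        expo, resid = refit_exposures(mat, sigs)
        assert (expo.exposures.iloc[0] == 0).all()

    def test_against_grid_oracle_3channel(self):
        """Brute-force grid search on a 3-channel, 2-signature toy."""
        S = np.array([[0.7, 0.1], [0.2, 0.2], [0.1, 0.7]])
        m = np.array([50.0, 30.0, 40.0])
        grid = np.linspace(0, 200, 2001)
        best = min(
            ((a, b) for a in grid for b in grid[::10]),
            key=lambda ab: np.sum((m - S @ np.array(ab)) ** 2),
        )
        from scipy.optimize import nnls

        x, _ = nnls(S, m)
        assert np.sum((m - S @ x) ** 2) <= np.sum((m - S @ np.array(best)) ** 2) + 1e-6

    def test_poisson_noise_mixture_within_5pp(self, truth_sigs):
        rng = np.random.default_rng(40)
        for f in (0.5, 0.83):
            p = truth_sigs.to_numpy() @ np.array([f, 1 - f])
            counts = rng.poisson(p * 30_000)
            mat = _matrix(counts[None, :])
            sigs = SignatureSet(scheme="SBS96", profiles=truth_sigs)
            expo, _ = refit_exposures(mat, sigs)
            frac = expo.fractions().iloc[0, 0]
            assert abs(frac - f) <= 0.05


class TestBootstrap:
    def test_ci_covers_point_and_shrinks(self, truth_sigs):
        sigs = SignatureSet(scheme="SBS96", profiles=truth_sigs)
        p = truth_sigs.to_numpy() @ np.array([0.7, 0.3])
        out = {}
        for n in (2_000, 8_000):
            counts = pd.Series(np.rint(p * n), index=SBS96_LABELS)
            ci = bootstrap_exposures(counts, sigs, n_boot=200, seed=50)
            assert ((ci["ci_low"] <= ci["fraction"] + 1e-9)
                    & (ci["fraction"] <= ci["ci_high"] + 1e-9)).all()
            out[n] = (ci["ci_high"] - ci["ci_low"]).iloc[0]
        # quadrupling the mutation count halves the width, approximately
        assert out[8_000] == pytest.approx(out[2_000] / 2, rel=0.5)

    def test_degenerate_single_channel(self, truth_sigs):
        sigs = SignatureSet(scheme="SBS96", profiles=truth_sigs)
        counts = pd.Series(0.0, index=SBS96_LABELS)
        # a channel carried by the dominant signature only
        lab = truth_sigs.index[(truth_sigs.iloc[:, 0] > 0)
                               & (truth_sigs.iloc[:, 1] == 0)][0]
        counts[lab] = 500
        ci = bootstrap_exposures(counts, sigs, n_boot=150, seed=51)
        assert ci.loc[truth_sigs.columns[0], "fraction"] == pytest.approx(1.0)
        assert ci.loc[truth_sigs.columns[0], "ci_high"] - \
            ci.loc[truth_sigs.columns[0], "ci_low"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_sample_errors(self, truth_sigs):
        sigs = SignatureSet(scheme="SBS96", profiles=truth_sigs)
        with pytest.raises(ValueError):
            bootstrap_exposures(pd.Series(0.0, index=SBS96_LABELS), sigs,
                                n_boot=100, seed=1)
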