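"""Tests for the BOLD pipeline: PCA, GLM, nulls, modularity, cartography."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gainreset.fmri import (
    CartographicProfile,
    ParcelDataset,
    SWITCH_REGRESSOR,
    beta_gradient,
    block_resample_null,
    build_event_design,
    canonical_hrf,
    cartography,
    cartographic_correlation,
    consensus_louvain,
    group_pca,
    louvain_signed,
    mbd_energy,
    pc_glm,
    signed_modularity,
)
from gainreset.synth import BoldSimSpec, gen_bold_cohort


@pytest.fixture(scope="module")
def clean_cohort():
    """Low-noise cohort where the three planted components dominate."""
    return gen_bold_cohort(
        BoldSimSpec(n_subjects=6, module_signal_sd=0.1, noise_sd=0.5), seed=2
    )


class TestGroupPCA:
    def test_planted_map_recovery(self, clean_cohort):
        ds, truth = clean_cohort
        g = group_pca(ds, k=3)
        for k in range(3):
            best = max(
                abs(np.corrcoef(g.loadings[:, k], truth.maps[:, j])[0, 1])
                for j in range(3)
            )
            assert best > 0.95

    def test_subject_order_invariance(self, clean_cohort):
        ds, _ = clean_cohort
        g1 = group_pca(ds, k=2)
        ds_rev = ParcelDataset(ds.data[::-1], ds.events, ds.tr_s)
        g2 = group_pca(ds_rev, k=2)
        for k in range(2):
            r = np.corrcoef(g1.loadings[:, k], g2.loadings[:, k])[0, 1]
            assert abs(r) > 0.9999

    def test_variance_explained_stable_under_region_duplication(self, clean_cohort):
        ds, _ = clean_cohort
        g1 = group_pca(ds, k=2)
        dup = [np.vstack([d, d[:1]]) for d in ds.data]
        g2 = group_pca(ParcelDataset(dup, ds.events, ds.tr_s), k=2)
        # one duplicated region among 375 barely moves the variance shares
        assert np.allclose(g1.variance_explained, g2.variance_explained, atol=0.2)

    def test_constant_region_raises(self, clean_cohort):
        ds, _ = clean_cohort
        bad = [d.copy() for d in ds.data]
        bad[0][3] = 1.0
        with pytest.raises(ValueError, match="region"):
            group_pca(ParcelDataset(bad, ds.events, ds.tr_s))


class TestHRF:
    def test_impulse_convolution_returns_kernel(self):
        h = canonical_hrf(2.0)
        imp = np.zeros(40)
        imp[0] = 1.0
        out = np.convolve(imp, h)[:40]
        assert np.allclose(out[: len(h)], h)

    def test_onset_is_zero_and_peak_near_five_seconds(self):
        h = canonical_hrf(0.5)
        assert h[0] == 0.0
        t_peak = np.argmax(h) * 0.5
        assert 4.0 <= t_peak <= 6.5

    def test_sampled_integral_matches_fine_grid(self):
        h = canonical_hrf(0.1)
        fine = canonical_hrf(0.001)
        coarse_integral = np.trapezoid(h, dx=0.1)
        fine_integral = np.trapezoid(fine, dx=0.001)
        assert abs(coarse_integral - fine_integral) / abs(fine_integral) < 0.01

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


def _simple_events(n_sets=10, switch=9, seed=None):
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for s in range(n_sets):
        sw = switch if seed is None else int(rng.integers(6, 13))
        for img in range(1, 16):
            rows.append(
                {
                    "subject": 0,
                    "set_id": s,
                    "image_index": img,
                    "onset_s": t,
                    "is_switch": img == sw,
                }
            )
            t += 2.0
        t += 4.0
    return pd.DataFrame(rows), int(np.ceil(t / 2.0)) + 17


class TestPCGLM:
    def test_exact_recovery_of_planted_regressor(self):
        events, n_vol = _simple_events()
        design = build_event_design(events, n_vol)
        y = 2.0 * design.matrix[:, SWITCH_REGRESSOR]
        res = pc_glm(y, design)
        expected = np.zeros(9)
        expected[SWITCH_REGRESSOR] = 2.0
        assert np.allclose(res.betas, expected, atol=1e-8)
        # residuals orthogonal to the design at machine precision
        assert np.max(np.abs(design.matrix.T @ res.residuals)) < 1e-6

    def test_pvalues_uniform_under_null(self):
        events, n_vol = _simple_events(n_sets=8, seed=1)
        design = build_event_design(events, n_vol)
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(150):
            res = pc_glm(rng.standard_normal(n_vol), design)
            pvals.extend(res.pvalues)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_length_mismatch(self):
        events, n_vol = _simple_events()
        design = build_event_design(events, n_vol)
        with pytest.raises(ValueError):
            pc_glm(np.zeros(n_vol - 5), design)


class TestBetaGradient:
    def test_constant_betas_zero(self):
        assert np.allclose(beta_gradient(np.full(9, 1.3)), 0.0)

    def test_peak_into_switch(self):
        b = np.zeros(9)
        b[4] = 1.0
        g = beta_gradient(b)
        assert np.argmax(np.abs(g)) in (3, 4)
        assert g[3] == 1.0 and g[4] == -1.0


class TestBlockResampleNull:
    def test_same_seed_identical(self):
        events, n_vol = _simple_events(n_sets=6, seed=3)
        y = np.random.default_rng(1).standard_normal(n_vol)
        n1, t1 = block_resample_null(y, events, n_perm=50, seed=9)
        n2, t2 = block_resample_null(y, events, n_perm=50, seed=9)
        assert np.array_equal(n1, n2)

    def test_planted_effect_exceeds_threshold(self):
        events, n_vol = _simple_events(n_sets=12, seed=4)
        design = build_event_design(events, n_vol)
        rng = np.random.default_rng(2)
        noise = rng.standard_normal(n_vol)
        y = 10.0 * noise.std() * design.matrix[:, SWITCH_REGRESSOR] + noise
        obs = abs(pc_glm(y, design).betas[SWITCH_REGRESSOR])
        _, thr = block_resample_null(y, events, n_perm=200, seed=5)
        assert obs > thr[SWITCH_REGRESSOR]

    def test_single_set_raises(self):
        events, n_vol = _simple_events(n_sets=1)
        with pytest.raises(ValueError):
            block_resample_null(np.zeros(n_vol), events, n_perm=10, seed=0)


class TestMBD:
    def test_energy_examples(self):
        tab = mbd_energy(np.array([1.0, 2.0]), np.array([1.0, np.exp(-1.0)]))
        assert tab["energy"].iloc[0] == 0.0
        assert np.isclose(tab["energy"].iloc[1], 1.0)
        assert np.isclose(tab["depth"].iloc[1], 0.5)

    def test_zero_probability_capped(self):
        tab = mbd_energy(np.array([1.0]), np.array([0.0]), p_min=1e-6)
        assert np.isclose(tab["energy"].iloc[0], np.log(1e6))


class TestSignedModularity:
    def test_two_cliques(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        assert np.isclose(signed_modularity(W, np.array([0, 0, 1, 1])), 0.5)

    def test_single_module_null_identity(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert np.isclose(signed_modularity(W, np.zeros(5)), 0.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            signed_modularity(np.zeros((3, 3)), np.zeros(3))

    def test_louvain_attains_exhaustive_maximum_on_toys(self):
        """Louvain consensus matches brute-force max Q_T on 6-node graphs."""

        def all_partitions(n):
            def rec(k):
                if k == 0:
                    yield []
                    return
                for p in rec(k - 1):
                    for i in range(len(p)):
                        yield p[:i] + [p[i] + [k - 1]] + p[i + 1 :]
                    yield p + [[k - 1]]

            yield from rec(n)

        rng = np.random.default_rng(7)
        for trial in range(3):
            W = np.zeros((6, 6))
            for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
                W[i, j] = W[j, i] = rng.uniform(0.5, 1.5)
            W[2, 3] = W[3, 2] = rng.uniform(0.0, 0.3)
            W[0, 5] = W[5, 0] = -rng.uniform(0.0, 0.5)
            best_q = max(
                signed_modularity(W, _labels_from(p, 6)) for p in all_partitions(6)
            )
            lab = consensus_louvain(W, reps=20, seed=trial)
            assert np.isclose(signed_modularity(W, lab), best_q, atol=1e-9)


def _labels_from(partition, n):
    lab = np.zeros(n, dtype=int)
    for k, grp in enumerate(partition):
        lab[grp] = k
    return lab


class TestConsensusLouvain:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        W = rng.random((20, 20))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        a = consensus_louvain(W, reps=12, seed=4)
        b = consensus_louvain(W, reps=12, seed=4)
        assert np.array_equal(a, b)

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        # block structure so the partition is stable
        W = np.kron(np.eye(3), np.ones((5, 5))) + 0.05 * rng.random((15, 15))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        lab = consensus_louvain(W, gamma_range=(1.0,), reps=12, seed=0)
        perm = rng.permutation(15)
        lab_p = consensus_louvain(
            W[np.ix_(perm, perm)], gamma_range=(1.0,), reps=12, seed=0
        )
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(lab[perm], lab_p) == 1.0

    def test_planted_modules_recovered_from_default_cohort(self):
        """Louvain consensus on group FC finds the three planted modules."""
        ds, truth = gen_bold_cohort(BoldSimSpec(n_subjects=6), seed=11)
        fc = np.mean([np.corrcoef(d) for d in ds.data], axis=0)
        np.fill_diagonal(fc, 0.0)
        labels = consensus_louvain(fc, reps=24, seed=3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth.module_labels, labels) == 1.0


class TestCartography:
    def test_within_module_only(self):
        W = np.kron(np.eye(2), np.ones((3, 3)) - np.eye(3))
        prof = cartography(W, np.array([0, 0, 0, 1, 1, 1]))
        assert np.allclose(prof.participation, 0.0)
        assert np.allclose(prof.module_z, 0.0)

    def test_even_spread_over_modules(self):
        # node 0 connects once into each of 3 modules
        W = np.zeros((7, 7))
        for j in (1, 3, 5):
            W[0, j] = W[j, 0] = 1.0
        labels = np.array([0, 0, 0, 1, 1, 2, 2])
        prof = cartography(W, labels)
        assert np.isclose(prof.participation[0], 1 - 3 * (1 / 3) ** 2)

    def test_isolated_node_flagged(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.warns(UserWarning, match="isolated"):
            prof = cartography(W, np.array([0, 0, 1, 1]))
        assert prof.participation[2] == 0.0


class TestCartographicCorrelation:
    def _profiles(self, rng, n_subj, shift):
        profs = []
        for s in range(n_subj):
            P = np.clip(rng.random(60) + shift[s], 0, 1)
            z = np.clip(rng.standard_normal(60) * 0.3, -1, 1)
            profs.append(CartographicProfile(P, z))
        return profs

    def test_planted_correlation_detected(self):
        rng = np.random.default_rng(0)
        n_subj = 12
        beta = np.linspace(-1, 1, n_subj)
        profs = self._profiles(rng, n_subj, shift=0.4 * beta)
        res = cartographic_correlation(profs, beta, n_perm=300, seed=1, n_bins=21)
        sig_r = res["r"][res["significant"]]
        assert len(sig_r) > 0

    def test_constant_betas_excluded(self):
        rng = np.random.default_rng(1)
        profs = self._profiles(rng, 6, shift=np.zeros(6))
        with pytest.warns(UserWarning, match="constant"):
            res = cartographic_correlation(profs, np.ones(6), n_perm=10, seed=0)
        assert np.all(np.isnan(res["r"]))

    def test_too_few_subjects(self):
        rng = np.random.default_rng(2)
        profs = self._profiles(rng, 3, shift=np.zeros(3))
        with pytest.raises(ValueError):
            cartographic_correlation(profs, np.arange(3.0), n_perm=10)
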