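"""Feature construction, CCA, component labeling, drives, projections."""

import numpy as np
import pytest
from scipy.linalg import eig

from claw_cbgt.claw import DtTertiles
from claw_cbgt.config import default_config
from claw_cbgt.ensembles import (
    DDM_COLUMNS,
    FEATURE_NAMES,
    EnsembleModel,
    build_feature_matrix,
    drive_timeseries,
    feature_vector_from_means,
    fit_cca,
    label_components,
    trial_drives,
    zone_projection,
)
from claw_cbgt.populations import ALL_POPULATIONS, POP_INDEX, swap_channels
from claw_cbgt.simulate import RateTraceSet, TrialRecord


def _trial_from_means(means: dict, n_bins=10, dt=100.0, choice="left"):
    rates = np.zeros((18, n_bins))
    for p, v in means.items():
        rates[POP_INDEX[p]] = v
    return TrialRecord(
        rates=rates, decision_time=dt, choice=choice,
        phase_marks={"stim_onset": 2, "decision_end": n_bins - 1,
                     "consolidation_end": n_bins - 1},
    )


def _uniform_means(value=10.0):
    return {p: value for p in ALL_POPULATIONS}


class TestFeatureMatrix:
    def test_symmetric_rates_zero_diffs(self):
        ts = RateTraceSet()
        ts.add(default_config(), [_trial_from_means(_uniform_means())])
        F = build_feature_matrix(ts)
        for j, name in enumerate(FEATURE_NAMES):
            if name.endswith("_diff"):
                assert F[0, j] == 0.0

    def test_doubling_thalamus_scales_sum_only(self):
        m1, m2 = _uniform_means(), _uniform_means()
        m2["Th-L"] *= 2
        m2["Th-R"] *= 2
        ts = RateTraceSet()
        ts.add(default_config(), [_trial_from_means(m1)])
        ts.add(default_config(), [_trial_from_means(m2)])
        F = build_feature_matrix(ts)
        j_sum = FEATURE_NAMES.index("Th_sum")
        j_diff = FEATURE_NAMES.index("Th_diff")
        assert F[1, j_sum] == 2 * F[0, j_sum]
        assert F[1, j_diff] == F[0, j_diff] == 0.0

    def test_hand_computed_two_network_toy(self):
        m1 = _uniform_means(0.0)
        m1.update({"Cx-L": 12.0, "Cx-R": 8.0, "CxI": 3.0})
        m2 = _uniform_means(0.0)
        m2.update({"GPi-L": 40.0, "GPi-R": 50.0, "FSI": 7.0})
        ts = RateTraceSet()
        ts.add(default_config(), [_trial_from_means(m1)])
        ts.add(default_config(), [_trial_from_means(m2)])
        F = build_feature_matrix(ts)
        assert F[0, FEATURE_NAMES.index("Cx_sum")] == pytest.approx(20.0)
        assert F[0, FEATURE_NAMES.index("Cx_diff")] == pytest.approx(4.0)
        assert F[0, FEATURE_NAMES.index("CxI")] == pytest.approx(3.0)
        assert F[1, FEATURE_NAMES.index("GPi_sum")] == pytest.approx(90.0)
        assert F[1, FEATURE_NAMES.index("GPi_diff")] == pytest.approx(-10.0)
        assert F[1, FEATURE_NAMES.index("FSI")] == pytest.approx(7.0)


def _random_fd(rng, n=200, noise=0.0):
    F = rng.normal(size=(n, 18))
    M = rng.normal(size=(18, 4)) * 0.0
    # D depends on 4 F columns exactly
    M[0, 0] = 1.0
    M[3, 1] = -0.7
    M[5, 2] = 0.5
    M[9, 3] = 1.2
    D = F @ M + noise * rng.normal(size=(n, 4))
    return F, D


class TestCCA:
    def test_exact_linear_dependence(self, rng):
        F, D = _random_fd(rng)
        model = fit_cca(F, D, k=3)
        assert np.all(model.correlations > 1 - 1e-6)

    def test_planted_factor_strength(self, rng):
        n = 200
        factor = rng.normal(size=n)
        F = rng.normal(size=(n, 18))
        F[:, 2] = factor + 0.3 * rng.normal(size=n)
        D = rng.normal(size=(n, 4)) * 1.0
        D[:, 1] = factor + 0.3 * rng.normal(size=n)
        model = fit_cca(F, D, k=3)
        # planted correlation corr(x, y) with x = f + .3e, y = f + .3e'
        planted = 1 / (1 + 0.09)
        assert model.correlations[0] == pytest.approx(planted, abs=0.05)

    def test_matches_brute_force_eigensolution(self, rng):
        # 5-feature toy: canonical correlations from the generalized
        # eigenproblem inv(Sxx) Sxy inv(Syy) Syx
        n = 300
        F = rng.normal(size=(n, 5))
        D = F @ rng.normal(size=(5, 4)) + rng.normal(size=(n, 4))
        model = fit_cca(F, D, k=3)
        X = (F - F.mean(0)) / F.std(0, ddof=1)
        Y = (D - D.mean(0)) / D.std(0, ddof=1)
        Sxx = X.T @ X / (n - 1)
        Syy = Y.T @ Y / (n - 1)
        Sxy = X.T @ Y / (n - 1)
        M = np.linalg.inv(Sxx) @ Sxy @ np.linalg.inv(Syy) @ Sxy.T
        vals = np.sort(np.real(eig(M)[0]))[::-1]
        expect = np.sqrt(np.clip(vals[:3], 0, 1))
        assert np.allclose(model.correlations, expect, atol=1e-8)

    def test_affine_rescaling_invariance(self, rng):
        F, D = _random_fd(rng, noise=0.5)
        m0 = fit_cca(F, D, k=3)
        F2 = F.copy()
        F2[:, 4] = 3.5 * F2[:, 4] - 7.0
        D2 = D.copy()
        D2[:, 2] = -2.0 * D2[:, 2] + 1.0
        m1 = fit_cca(F2, D2, k=3)
        assert np.allclose(m0.correlations, m1.correlations, atol=1e-8)

    def test_sign_convention(self, rng):
        F, D = _random_fd(rng, noise=0.5)
        model = fit_cca(F, D, k=3)
        for j in range(3):
            i = np.argmax(np.abs(model.U[:, j]))
            assert model.U[i, j] > 0

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_cca(rng.normal(size=(30, 18)), rng.normal(size=(29, 4)))


def _planted_model(order=(0, 1, 2), flip=None):
    """U, V with the canonical qualitative patterns: component 0 = choice
    (diff features, v), 1 = responsiveness (a and t same sign), 2 = pliancy
    (a and t opposite signs)."""
    U = np.zeros((18, 3))
    V = np.zeros((4, 3))
    diff_rows = [j for j, n in enumerate(FEATURE_NAMES) if n.endswith("_diff")]
    sum_rows = [j for j, n in enumerate(FEATURE_NAMES) if n.endswith("_sum")]
    U[diff_rows, 0] = 1.0
    V[DDM_COLUMNS.index("v"), 0] = 1.0
    U[sum_rows[:4], 1] = 1.0
    V[DDM_COLUMNS.index("a"), 1] = -0.8
    V[DDM_COLUMNS.index("t"), 1] = -0.6
    U[sum_rows[4:], 2] = 1.0
    V[DDM_COLUMNS.index("a"), 2] = 0.8
    V[DDM_COLUMNS.index("t"), 2] = -0.6
    U, V = U[:, order], V[:, order]
    if flip is not None:
        U[:, flip] *= -1
        V[:, flip] *= -1
    return EnsembleModel(
        U=U, V=V, correlations=np.array([0.9, 0.8, 0.7]),
        feature_means=np.zeros(18), feature_sds=np.ones(18),
        ddm_means=np.zeros(4), ddm_sds=np.ones(4),
    )


class TestLabeling:
    def test_planted_patterns_recovered(self):
        model = label_components(_planted_model())
        assert model.labels == {"choice": 0, "responsiveness": 1, "pliancy": 2}
        assert model.label_confident

    def test_order_invariance(self):
        model = label_components(_planted_model(order=(2, 0, 1)))
        # columns permuted: choice moved to column 1
        assert model.labels["choice"] == 1
        assert model.labels["responsiveness"] == 2
        assert model.labels["pliancy"] == 0

    def test_sign_invariance(self):
        model = label_components(_planted_model(flip=1))
        assert model.labels == {"choice": 0, "responsiveness": 1, "pliancy": 2}

    def test_assignment_is_bijection(self):
        model = label_components(_planted_model())
        assert sorted(model.labels.values()) == [0, 1, 2]


class TestDrives:
    def test_constant_rates_zero_drive(self):
        model = _planted_model()
        rec = _trial_from_means(_uniform_means())
        W = trial_drives(rec.decision_rates(), rec.stim_onset_bin, model)
        assert np.allclose(W, 0.0)

    def test_selector_matrix_reproduces_increments(self):
        model = _planted_model()
        model.U = np.zeros((18, 3))
        model.U[0, 0] = 1.0  # select Cx_sum increments
        rates = np.zeros((18, 4))
        rates[POP_INDEX["Cx-L"]] = [1.0, 2.0, 4.0, 7.0]
        rec = TrialRecord(
            rates=rates, decision_time=40.0, choice="left",
            phase_marks={"stim_onset": 0, "decision_end": 3,
                         "consolidation_end": 3},
        )
        W = trial_drives(rec.decision_rates(), 0, model)
        assert np.allclose(W[:, 0], [0.0, 1.0, 2.0, 3.0])
        assert np.allclose(W[:, 1:], 0.0)

    def test_hand_matrix_product(self):
        model = _planted_model()
        U = np.zeros((18, 3))
        U[0, 0], U[1, 1], U[2, 2] = 2.0, -1.0, 0.5
        model.U = U
        rates = np.zeros((18, 3))
        rates[POP_INDEX["Cx-L"]] = [1.0, 3.0, 3.0]   # Cx_sum and Cx_diff move
        rates[POP_INDEX["dSPN-L"]] = [0.0, 1.0, 2.0]  # dSPN_sum moves
        rec = TrialRecord(
            rates=rates, decision_time=30.0, choice="left",
            phase_marks={"stim_onset": 0, "decision_end": 2,
                         "consolidation_end": 2},
        )
        W = trial_drives(rec.decision_rates(), 0, model)
        # dF bin1 = [Cx_sum +2, Cx_diff +2, dSPN_sum +1, ...]
        assert W[1, 0] == pytest.approx(4.0)   # 2 * 2
        assert W[1, 1] == pytest.approx(-2.0)  # -1 * 2
        assert W[1, 2] == pytest.approx(0.5)   # 0.5 * 1

    def test_channel_swap_negates_diffs_preserves_sums(self):
        means = _uniform_means()
        means["Cx-L"], means["Cx-R"] = 14.0, 9.0
        f = feature_vector_from_means(
            np.array([means[p] for p in ALL_POPULATIONS]))
        swapped = {swap_channels(p): v for p, v in means.items()}
        fs = feature_vector_from_means(
            np.array([swapped[p] for p in ALL_POPULATIONS]))
        for j, name in enumerate(FEATURE_NAMES):
            if name.endswith("_diff"):
                assert fs[j] == pytest.approx(-f[j])
            else:
                assert fs[j] == pytest.approx(f[j])

    def test_short_trial_excluded(self):
        model = label_components(_planted_model())
        rec = _trial_from_means(_uniform_means(), n_bins=3)
        rec.phase_marks["stim_onset"] = 2  # single decision bin
        ts = RateTraceSet()
        ts.add(default_config(), [rec])
        tert = DtTertiles(cut_low=150.0, cut_high=300.0)
        with pytest.warns(UserWarning, match="shorter"):
            series = drive_timeseries(ts, model, tert)
        assert series.groups == {}


class TestZoneProjection:
    def _setup(self):
        from claw_cbgt.binarize import binarize_network
        from claw_cbgt.claw import extract_sequences, estimate_transitions, prune_graph, partition_zones
        from claw_cbgt.simulate import run_experiment
        cfg = default_config()
        _, trials = run_experiment(cfg, 10, seed=21)
        ts = RateTraceSet()
        ts.add(cfg, trials)
        bset, _ = binarize_network(trials)
        seqs = extract_sequences(bset)
        graph = prune_graph(estimate_transitions(seqs))
        part = partition_zones(graph)
        return ts, [seqs], part

    def test_zero_feature_change_zero_projection(self):
        model = label_components(_planted_model())
        W = np.zeros((3, 3))
        P = W @ model.V.T
        assert np.allclose(P, 0.0)

    def test_hand_double_product(self):
        # explicit (dF U) V^T on a 2-feature/2-parameter toy embedded in
        # the full shapes
        model = _planted_model()
        model.U = np.zeros((18, 3))
        model.U[0, 0], model.U[1, 0] = 1.0, 2.0
        model.V = np.zeros((4, 3))
        model.V[0, 0], model.V[1, 0] = 3.0, -1.0
        dF = np.zeros((1, 18))
        dF[0, 0], dF[0, 1] = 2.0, 0.5
        W = dF @ model.U
        P = W @ model.V.T
        assert W[0, 0] == pytest.approx(3.0)
        assert P[0, 0] == pytest.approx(9.0)
        assert P[0, 1] == pytest.approx(-3.0)

    def test_projection_runs_on_simulated_network(self):
        ts, seqs, part = self._setup()
        model = label_components(_planted_model())
        ddm_table = np.tile([1.0, 0.5, 0.2, 0.5], (1, 1))
        proj = zone_projection(ts, seqs, part, model, ddm_table)
        for pair, d in proj.pairs.items():
            assert d["W"].shape[1] == 3
            assert d["P"].shape[1] == 4
            assert d["n_networks"] >= 1
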