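"""Raised-cosine basis, Poisson fitting, per-trial scoring and classification."""

import numpy as np
import pytest

from prepcirc.glm import (
    BasisSpec,
    GlmFit,
    _linfit_r2,
    bin_spikes,
    build_design,
    classify_unit,
    fit_poisson,
    raised_cosine_basis,
    score_fit,
)
from prepcirc.session import BehaviorTrace, EventSeries, Session, TrialTable, Unit


def _flat_session(duration=40.0, rewards=(10.0, 30.0), licks=(), speed=20.0):
    n = int(duration * 100)
    return Session(
        session_id="glm",
        units=[Unit("u", "ALM")],
        spikes={"u": np.empty(0)},
        behavior=BehaviorTrace(100.0, np.full(n, float(speed)), np.zeros(n)),
        events=EventSeries(reward_times=np.array(rewards), lick_times=np.array(licks)),
        trials=TrialTable(
            np.arange(len(rewards)),
            np.array(rewards) - 8.0,
            np.array(rewards),
            ["none"] * len(rewards),
        ),
    )


class TestBasis:
    def test_bump_closed_form(self):
        basis, centers = raised_cosine_basis((-2.0, 2.0), spacing=0.025)
        t = -2.0 + 0.001 * np.arange(basis.shape[0])
        j = len(centers) // 2
        c = centers[j]
        i_c = int(round((c + 2.0) / 0.001))
        assert basis[i_c, j] == pytest.approx(1.0, abs=1e-9)
        for edge in (c - 0.05, c + 0.05):  # 2*spacing away
            i_e = int(round((edge + 2.0) / 0.001))
            if 0 <= i_e < basis.shape[0]:
                assert basis[i_e, j] == pytest.approx(0.0, abs=1e-9)
        assert np.all(basis >= 0)
        # interior bumps attain 1; pad bumps peak outside the sampled window
        assert np.allclose(basis[:, 2:-2].max(axis=0), 1.0, atol=1e-6)

    def test_partition_of_unity_interior(self):
        basis, _ = raised_cosine_basis((-2.0, 2.0), spacing=0.025)
        total = basis.sum(axis=1)
        interior = total[100:-100]
        # bumps at quarter-period spacing sum to a constant (2) inside the window
        np.testing.assert_allclose(interior, 2.0, atol=1e-6)

    def test_center_count_and_padding(self):
        _, centers = raised_cosine_basis((-2.0, 2.0), spacing=0.025, pad=2)
        # 160 spacing intervals -> 161 interior centers, plus 2 pad on each side
        assert len(centers) == 161 + 4
        assert centers[0] == pytest.approx(-2.0 - 2 * 0.025)
        assert centers[-1] == pytest.approx(2.0 + 2 * 0.025)


class TestDesign:
    def test_single_event_column_is_shifted_bump(self):
        s = _flat_session(rewards=(20.0,))
        design = build_design(s, covariates=("reward",))
        X = design.X.toarray()
        sl = design.columns["reward"]
        col = X[:, sl.start + 5]
        c = design.centers["reward"][5]
        nz = np.flatnonzero(col)
        t_nz = (nz + 0.5) * design.dt
        assert abs(t_nz.mean() - (20.0 + c)) < 0.003
        assert col.max() == pytest.approx(1.0, abs=1e-6)

    def test_two_overlapping_events_columns_add(self):
        s1 = _flat_session(rewards=(20.0,))
        s2 = _flat_session(rewards=(20.5,))
        s12 = _flat_session(rewards=(20.0, 20.5))
        sl = build_design(s1, ("reward",)).columns["reward"]
        a = build_design(s1, ("reward",)).X.toarray()[:, sl]
        b = build_design(s2, ("reward",)).X.toarray()[:, sl]
        ab = build_design(s12, ("reward",)).X.toarray()[:, sl]
        np.testing.assert_allclose(ab, a + b, atol=1e-9)

    def test_column_count_bookkeeping(self):
        s = _flat_session(rewards=(10.0, 30.0), licks=(9.5, 9.7))
        design = build_design(s, covariates=("reward", "lick", "run"))
        n_bumps = len(design.centers["reward"]) + len(design.centers["lick"])
        assert design.X.shape[1] == n_bumps + 2  # + speed + intercept

    def test_empty_covariate_omitted_with_warning(self):
        s = _flat_session(licks=())
        with pytest.warns(UserWarning, match="lick"):
            design = build_design(s, covariates=("reward", "lick"))
        assert "lick" not in design.columns


class TestPoissonFit:
    def test_intercept_only_recovers_log_rate(self, rng):
        lam = 15.0  # Hz at 1 ms bins
        n = 200_000
        y = (rng.random(n) < lam * 1e-3).astype(float)
        X = np.ones((n, 1))
        res = fit_poisson(X, y, intercept_col=0)
        se = 1.0 / np.sqrt(lam * 1e-3 * n)
        assert abs(res.weights[0] - np.log(lam * 1e-3)) < 3 * se
        assert res.converged

    def test_all_zero_response_no_crash(self):
        X = np.column_stack([np.ones(1000), np.linspace(-1, 1, 1000)])
        res = fit_poisson(X, np.zeros(1000), intercept_col=0, raise_on_failure=False)
        assert np.isfinite(res.weights).all()
        assert res.weights[0] < -5.0  # very negative intercept, guarded

    def test_matches_statsmodels_on_dense_problem(self, rng):
        import statsmodels.api as sm

        n, p = 5000, 4
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1)) * 0.3])
        beta_true = np.array([-3.0, 0.4, -0.2, 0.1])
        y = rng.poisson(np.exp(X @ beta_true))
        ours = fit_poisson(X, y.astype(float), ridge=0.0, intercept_col=0)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(ours.weights, ref.params, atol=1e-5)

    def test_sparse_and_dense_agree(self, rng):
        import scipy.sparse as sp

        n = 3000
        X = np.column_stack([np.ones(n), (rng.random(n) < 0.1).astype(float)])
        y = (rng.random(n) < 0.02).astype(float)
        d = fit_poisson(X, y, intercept_col=0)
        s = fit_poisson(sp.csr_matrix(X), y, intercept_col=0)
        np.testing.assert_allclose(d.weights, s.weights, atol=1e-7)


class TestScoring:
    def test_r2_trivial_cases(self, rng):
        y = rng.standard_normal(500)
        assert _linfit_r2(y * 2.0 + 3.0, y) == pytest.approx(1.0)
        assert _linfit_r2(np.full(500, 1.3), y) == pytest.approx(0.0)
        assert _linfit_r2(y, np.full(500, 2.0)) == pytest.approx(1.0)

    def test_classification_invariant_to_time_shift(self):
        from prepcirc.synth import GenConfig, UnitSpec, generate_session
        from prepcirc.glm import classify_session_units

        cfg = GenConfig(n_trials=10, roster=[UnitSpec("u", "ALM", "type2", amp=20.0)])
        session, _, _ = generate_session(cfg, 17)
        base = classify_session_units(session, covariates=("reward", "run"))["u"]

        shift = 5.0
        n_pad = int(shift * session.behavior.sample_rate)
        shifted = Session(
            session_id="shifted",
            units=session.units,
            spikes={"u": session.spikes["u"] + shift},
            behavior=BehaviorTrace(
                session.behavior.sample_rate,
                np.concatenate([session.behavior.running_speed[:n_pad],
                                session.behavior.running_speed]),
                np.concatenate([session.behavior.corridor_position[:n_pad],
                                session.behavior.corridor_position]),
            ),
            events=EventSeries(
                reward_times=session.events.reward_times + shift,
                lick_times=session.events.lick_times + shift,
            ),
            trials=TrialTable(
                session.trials.index,
                session.trials.start_time + shift,
                session.trials.reward_time + shift,
                list(session.trials.photo_mode),
            ),
        )
        moved = classify_session_units(shifted, covariates=("reward", "run"))["u"]
        assert moved.unit_type == base.unit_type
        assert moved.mean_r2["reward_pre"] == pytest.approx(
            base.mean_r2["reward_pre"], abs=0.02
        )


class TestClassifyUnit:
    @staticmethod
    def _fit(pre, post, lick=0.0, run=0.0):
        return GlmFit(
            weights={},
            r2={},
            mean_r2={"reward_pre": pre, "reward_post": post, "lick": lick, "run": run},
            design=None,
        )

    def test_threshold_is_strict(self):
        cls = classify_unit(self._fit(0.17, 0.0))
        assert cls.unit_type == 0 and cls.classes == []

    @pytest.mark.parametrize(
        "pre, post, expected",
        [(0.3, 0.05, 1), (0.3, 0.3, 2), (0.05, 0.3, 3), (0.1, 0.1, 0)],
    )
    def test_type_from_subwindow_pattern(self, pre, post, expected):
        assert classify_unit(self._fit(pre, post)).unit_type == expected

    def test_every_passing_covariate_listed(self):
        cls = classify_unit(self._fit(0.3, 0.05, lick=0.25, run=0.18))
        assert cls.classes == ["lick", "reward", "run"]

    def test_sign_from_z_psth_epochs(self):
        centers = np.linspace(-3.95, 1.95, 60)
        z = np.where(centers < 0, 1.5, -0.8)
        cls = classify_unit(self._fit(0.3, 0.3), z, centers)
        assert cls.sign_pre == 1 and cls.sign_post == -1


def test_kernel_recovery_on_generator_data():
    """The fitted reward kernel correlates with the true intensity profile."""
    from prepcirc.synth import GenConfig, UnitSpec, generate_session
    from prepcirc.synth import _match_cues_to_rewards, _ramp_profile

    cfg = GenConfig(n_trials=60, roster=[UnitSpec("u", "ALM", "type2", amp=20.0)])
    session, _, _ = generate_session(cfg, 13)
    design = build_design(session, ("reward", "run"))
    y = bin_spikes(session.spikes["u"], design.n_bins)
    res = fit_poisson(design.X, y, intercept_col=design.intercept_col)
    basis, _ = raised_cosine_basis((-4.0, 2.0))
    kernel = basis @ res.weights[design.columns["reward"]]
    # oracle: average true type-2 intensity profile around rewards
    t = (np.arange(design.n_bins) + 0.5) * 1e-3
    rewards = session.events.reward_times
    cues = _match_cues_to_rewards(
        session.events.cue_times["checkerboard_rewarded"], rewards
    )
    prof = _ramp_profile(t, cues, rewards, "type2")
    true_kernel = np.zeros_like(kernel)
    n_used = 0
    for r in rewards:
        i = int(round((r - 4.0) / 1e-3))
        if i >= 0 and i + len(kernel) <= len(prof):
            true_kernel += prof[i : i + len(kernel)]
            n_used += 1
    true_kernel /= n_used
    c = np.corrcoef(kernel, true_kernel)[0, 1]
    assert c > 0.9
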