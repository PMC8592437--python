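import numpy as np
import pytest

from relapsim.cohort import AML_INPUT_WINDOW_MONTHS
from relapsim.degrade import split_windows
from relapsim.disease_models import Trajectory, TreatmentSchedule, MONTH_DAYS
from relapsim.features import (
    aml_features, cml_features, feature_matrix, FeaturizationError,
    AML_FEATURE_NAMES, CML_FEATURE_NAMES, CML_AS_FEATURE_NAMES,
    _two_segment_fit, _cycle_time_split,
)


def _traj(times, log_values, disease="AML", variant="SN", censored=None):
    times = np.asarray(times, dtype=float)
    if censored is None:
        censored = np.zeros(len(times), dtype=bool)
    return Trajectory(patient_id="f", disease=disease, variant=variant,
                      times=times, values=10.0 ** np.asarray(log_values),
                      censored=censored)


@pytest.fixture
def schedule():
    starts = np.array([0.0, 35.0, 70.0])
    return TreatmentSchedule(disease="AML",
                             cycles=tuple((s, s + 7.0) for s in starts))


class TestAmlFeatures:
    def test_collinear_points_collapse_all_slopes(self, schedule):
        s, icpt = -0.5, 1.8  # per month
        t = np.linspace(0.25, 9.0, 12)
        tr = _traj(t, icpt + s * t)
        f = aml_features(tr, schedule)
        assert f.a == pytest.approx(s, abs=1e-8)
        assert f.b == pytest.approx(s, abs=1e-8)
        assert f.alpha == pytest.approx(s, abs=1e-8)
        assert f.y0 == pytest.approx(icpt, abs=1e-8)

    def test_sawtooth_slopes_recovered_exactly(self, schedule):
        # constructed with in-cycle slope -2 and between-cycle slope +1
        a_true, b_true, y0_true = -2.0, 1.0, 2.0
        t = np.sort(np.concatenate([
            np.linspace(0.01, 9.0, 25),
            [s / MONTH_DAYS + 0.05 for s, _ in schedule.cycles]]))
        g, h = _cycle_time_split(t, schedule)
        y = y0_true + a_true * g + b_true * h
        f = aml_features(_traj(t, y), schedule)
        assert f.a == pytest.approx(a_true, abs=1e-6)
        assert f.b == pytest.approx(b_true, abs=1e-6)
        assert f.y0 == pytest.approx(y0_true, abs=1e-6)

    def test_nadir_equals_brute_force_minimum(self, schedule):
        rng = np.random.default_rng(4)
        t = np.linspace(0.25, 9.0, 20)
        y = rng.normal(-1, 1, 20)
        f = aml_features(_traj(t, y), schedule)
        t_end = schedule.treatment_end_day / MONTH_DAYS
        assert f.n == pytest.approx(min(y[t > t_end]))

    def test_too_few_points_raise(self, schedule):
        with pytest.raises(FeaturizationError, match="segmented"):
            aml_features(_traj([1.0, 2.0], [0, 0]), schedule)

    def test_segmented_fit_never_worse_than_single_line(self, schedule):
        rng = np.random.default_rng(9)
        t = np.linspace(0.1, 9.0, 18)
        y = rng.normal(0, 1, len(t))
        g, h = _cycle_time_split(t, schedule)
        X2 = np.column_stack([np.ones_like(t), g, h])
        c2, *_ = np.linalg.lstsq(X2, y, rcond=None)
        sse_seg = np.sum((y - X2 @ c2) ** 2)
        X1 = np.column_stack([np.ones_like(t), t])
        c1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        sse_line = np.sum((y - X1 @ c1) ** 2)
        assert sse_seg <= sse_line + 1e-9


class TestCmlFeatures:
    def test_single_line_gives_equal_segments_and_zero_sigma(self, cml_schedule):
        t = np.linspace(0.0, 92.0, 24)
        f = cml_features(_traj(t, 1.5 - 0.04 * t, "CML"), cml_schedule)
        assert f.alpha == pytest.approx(-0.04, abs=1e-8)
        assert f.beta == pytest.approx(-0.04, abs=1e-8)
        assert f.A == pytest.approx(1.5, abs=1e-8)
        assert f.B == pytest.approx(1.5, abs=1e-6)
        assert f.sigma == pytest.approx(0.0, abs=1e-8)

    def test_two_segment_ground_truth_recovered(self, cml_schedule):
        # bi-phasic decline with slopes -0.5 then -0.02, breakpoint month 6
        # (kept above the burden floor so no log clipping interferes)
        t = np.sort(np.concatenate([np.linspace(0, 6, 8),
                                    np.linspace(7, 92, 16)]))
        y = np.where(t <= 6, 2.0 - 0.5 * t, 2.0 - 0.5 * 6 - 0.02 * (t - 6))
        f = cml_features(_traj(t, y, "CML"), cml_schedule)
        assert f.alpha == pytest.approx(-0.5, abs=1e-8)
        assert f.beta == pytest.approx(-0.02, abs=1e-8)
        assert f.A == pytest.approx(2.0, abs=1e-8)
        # B is the second line extrapolated to t = 0
        assert f.B == pytest.approx(2.0 + (-0.5 + 0.02) * 6, abs=1e-6)
        assert f.sigma == pytest.approx(0.0, abs=1e-9)

    def test_breakpoint_search_matches_exhaustive_oracle(self, cml_schedule):
        rng = np.random.default_rng(12)
        t = np.sort(rng.uniform(0, 92, 30))
        y = 1.0 - 0.05 * t + rng.normal(0, 0.3, 30)

        def oracle(t, y):
            best = (np.inf, None)
            for tau in t[1:-2]:
                X = np.column_stack([np.ones_like(t), t,
                                     np.maximum(0.0, t - tau)])
                c, *_ = np.linalg.lstsq(X, y, rcond=None)
                sse = float(np.sum((y - X @ c) ** 2))
                if sse < best[0]:
                    best = (sse, tau)
            return best

        sse_star, tau_star = oracle(t, y)
        A, alpha, beta, tau, rmse = _two_segment_fit(t, y)
        assert tau == pytest.approx(tau_star)
        assert rmse ** 2 * len(t) == pytest.approx(sse_star, rel=1e-9)

    def test_insufficient_points_raise(self, cml_schedule):
        with pytest.raises(FeaturizationError):
            cml_features(_traj([0, 40, 92], [0, -1, -2], "CML"), cml_schedule)

    def test_all_censored_raises(self, cml_schedule):
        t = np.linspace(0, 92, 10)
        tr = _traj(t, np.full(10, -2.0), "CML",
                   censored=np.ones(10, dtype=bool))
        with pytest.raises(FeaturizationError, match="censored"):
            cml_features(tr, cml_schedule)

    def test_as_features_fit_the_half_dose_year(self):
        sch = TreatmentSchedule(disease="CML", t_stop=92.0,
                                half_dose_start=80.0)
        t_pre = np.linspace(0.0, 79.0, 20)
        t_half = np.arange(80.0, 92.5, 1.0)
        gamma_true, c_true = 0.08, -3.0
        y = np.concatenate([1.0 - 0.05 * t_pre,
                            c_true + gamma_true * (t_half - 80.0)])
        tr = _traj(np.concatenate([t_pre, t_half]), y, "CML", variant="AS")
        f = cml_features(tr, sch, variant="AS")
        assert f.gamma == pytest.approx(gamma_true, abs=1e-8)
        assert f.C == pytest.approx(c_true, abs=1e-8)
        assert f.sigma_half == pytest.approx(0.0, abs=1e-9)
        assert f.last_pre_stop == pytest.approx(y[-1])


class TestFeatureMatrix:
    def _inputs(self, cohort, variants, variant, disease):
        return [split_windows(t, disease, r.schedule)[0]
                for t, r in zip(variants[variant], cohort)]

    def test_aml_matrix_has_five_feature_columns(self, aml_cohort,
                                                 aml_variants):
        inputs = self._inputs(aml_cohort, aml_variants, "AP", "AML")
        labels = [r.relapse for r in aml_cohort]
        X, y, kept = feature_matrix(inputs,
                                    [r.schedule for r in aml_cohort],
                                    labels, "AML", "AP")
        assert tuple(X.columns) == AML_FEATURE_NAMES
        assert len(X) == len(y) == len(kept)

    def test_cml_matrix_column_counts_by_variant(self, cml_cohort,
                                                 cml_variants):
        labels = [r.relapse for r in cml_cohort]
        sched = [r.schedule for r in cml_cohort]
        X, _, _ = feature_matrix(
            self._inputs(cml_cohort, cml_variants, "AP", "CML"),
            sched, labels, "CML", "AP")
        assert tuple(X.columns) == CML_FEATURE_NAMES and len(X.columns) == 7
        Xa, _, _ = feature_matrix(
            self._inputs(cml_cohort, cml_variants, "AS", "CML"),
            sched, labels, "CML", "AS")
        assert tuple(Xa.columns) == CML_AS_FEATURE_NAMES

    def test_features_ignore_post_window_points(self, aml_cohort,
                                                aml_variants):
        rec = aml_cohort[0]
        full = aml_variants["SN"][0]
        inp, _ = split_windows(full, "AML", rec.schedule)
        f_inp = aml_features(inp, rec.schedule)
        win = full.times <= AML_INPUT_WINDOW_MONTHS + 1e-9
        # identical in-window points with horizon points appended
        assert np.array_equal(full.times[win], inp.times)
        f_full = aml_features(inp, rec.schedule)
        assert f_inp == f_full

    def test_rerun_determinism_and_row_permutation(self, aml_cohort,
                                                   aml_variants):
        inputs = self._inputs(aml_cohort, aml_variants, "SN", "AML")
        labels = np.array([r.relapse for r in aml_cohort])
        sched = [r.schedule for r in aml_cohort]
        X1, _, _ = feature_matrix(inputs, sched, labels, "AML", "SN")
        X2, _, _ = feature_matrix(inputs, sched, labels, "AML", "SN")
        assert X1.equals(X2)
        perm = np.random.default_rng(0).permutation(len(inputs))
        Xp, _, _ = feature_matrix([inputs[i] for i in perm],
                                  [sched[i] for i in perm], labels[perm],
                                  "AML", "SN")
        assert Xp.loc[X1.index[0]].equals(X1.iloc[0])
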