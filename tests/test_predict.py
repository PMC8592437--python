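import numpy as np
import pytest

from relapsim.cohort import CohortConfig, generate_cohort
from relapsim.degrade import DegradeConfig, make_variants, split_windows
from relapsim.predict import (
    PatientInput, Prediction, fit_mechanistic, predict_mm,
    MechanisticClassifier, FeatureLogisticClassifier,
    SequenceLSTMClassifier, encode_sequences, make_patient_inputs,
    _objective_factory,
)
from relapsim._lstm import BiLSTMNet
from relapsim.disease_models import TreatmentSchedule


@pytest.fixture(scope="module")
def aml_inputs(aml_cohort, aml_variants):
    out = {}
    for v in ("D", "SN", "AP"):
        out[v] = make_patient_inputs(
            aml_cohort,
            [split_windows(t, "AML", r.schedule)[0]
             for t, r in zip(aml_variants[v], aml_cohort)], v)
    return out


@pytest.fixture(scope="module")
def aml_labels(aml_cohort):
    return np.array([r.relapse for r in aml_cohort])


class TestMechanisticFit:
    def test_objective_vanishes_at_generating_parameters(self, aml_cohort,
                                                         aml_inputs):
        rec, inp = aml_cohort[0], aml_inputs["D"][0]
        obj = _objective_factory(inp, rec.parameters)
        theta_true = np.log10([rec.parameters.p_L, rec.parameters.t_QA_L])
        assert obj(theta_true) < 1e-8

    def test_one_sided_censored_residual_is_free_below_lod(self, aml_cohort,
                                                           aml_inputs):
        rec = aml_cohort[0]
        inp = aml_inputs["D"][0]
        cens = PatientInput(
            id=inp.id, disease="AML", variant="AP", times=inp.times,
            values=np.full_like(inp.values, 0.01),
            censored=np.ones(len(inp.times), dtype=bool),
            schedule=inp.schedule, lod=0.01)
        obj = _objective_factory(cens, rec.parameters)
        # the generating parameters simulate below the LOD at late times;
        # censored points where sim < lod must contribute exactly zero
        theta = np.log10([rec.parameters.p_L, rec.parameters.t_QA_L])
        from relapsim.disease_models import simulate
        tr = simulate(rec.parameters, rec.schedule, inp.times)
        expected = float(np.sum(np.maximum(
            0.0, np.log10(tr.values) - np.log10(0.01)) ** 2))
        assert obj(theta) == pytest.approx(expected, rel=1e-6)

    def test_noise_free_parameter_recovery(self, aml_cohort, aml_inputs):
        hits = 0
        for rec, inp in zip(aml_cohort[:12], aml_inputs["D"][:12]):
            f = fit_mechanistic(inp, seed=1)
            err = max(abs(f.params.p_L - rec.parameters.p_L)
                      / rec.parameters.p_L,
                      abs(f.params.t_QA_L - rec.parameters.t_QA_L)
                      / rec.parameters.t_QA_L)
            hits += err < 0.05
        assert hits >= 11

    def test_too_few_points_raise(self, aml_inputs):
        inp = aml_inputs["D"][0]
        short = PatientInput(id="s", disease="AML", variant="D",
                             times=inp.times[:1], values=inp.values[:1],
                             censored=inp.censored[:1],
                             schedule=inp.schedule, lod=0.01)
        with pytest.raises(ValueError, match="need"):
            fit_mechanistic(short)


class TestMechanisticClassifier:
    def test_self_consistency_on_dense_data(self, aml_cohort, aml_inputs,
                                            aml_labels):
        mm = MechanisticClassifier().fit(aml_inputs["D"])
        pred = mm.predict(aml_inputs["D"][:25])
        assert np.mean(pred == aml_labels[:25]) >= 0.95

    def test_deterministic_given_seed(self, aml_inputs):
        mm = MechanisticClassifier(random_state=3).fit(aml_inputs["AP"])
        a = mm.predict(aml_inputs["AP"][:6])
        b = mm.predict(aml_inputs["AP"][:6])
        np.testing.assert_array_equal(a, b)

    def test_scores_are_hard_labels(self, aml_inputs):
        mm = MechanisticClassifier().fit(aml_inputs["AP"])
        preds = mm.predictions(aml_inputs["AP"][:4])
        assert all(p.score in (0.0, 1.0) for p in preds)
        assert all(p.label == (p.score >= 0.5) for p in preds)


def _irls_oracle(X, y, lam):
    """Independent IRLS with ridge on weights (intercept unpenalized)."""
    X1 = np.column_stack([np.ones(len(X)), X])
    w = np.zeros(X1.shape[1])
    pen = lam * np.eye(X1.shape[1])
    pen[0, 0] = 0.0
    for _ in range(200):
        eta = X1 @ w
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p) + 1e-12
        z = eta + (y - p) / W
        A = X1.T @ (W[:, None] * X1) + pen
        w_new = np.linalg.solve(A, X1.T @ (W * z))
        if np.max(np.abs(w_new - w)) < 1e-12:
            w = w_new
            break
        w = w_new
    return w


class TestFeatureLogisticClassifier:
    def test_coefficients_match_irls_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 20) > 0)
        lam = 1e-4
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(C=1 / lam, solver="lbfgs", max_iter=5000,
                                 tol=1e-12).fit(X, y)
        w = _irls_oracle(X, y.astype(float), lam)
        assert np.allclose(clf.intercept_[0], w[0], atol=1e-3)
        assert np.allclose(clf.coef_[0], w[1:], atol=1e-3)

    def test_separable_training_data_is_fit_perfectly(self, aml_cohort,
                                                      aml_inputs):
        # labels redefined to be a perfect function of one feature
        from relapsim.features import feature_matrix
        inputs = aml_inputs["SN"]
        X, _, kept = feature_matrix(
            [i.as_trajectory() for i in inputs],
            [i.schedule for i in inputs],
            np.zeros(len(inputs)), "AML", "SN")
        y_sep = (X["n"] > X["n"].median()).to_numpy()
        glm = FeatureLogisticClassifier(disease="AML", variant="SN")
        kept_inputs = [inputs[i] for i in kept]
        glm.fit(kept_inputs, y_sep)
        assert np.mean(glm.predict(kept_inputs) == y_sep) == 1.0

    def test_probabilities_strictly_inside_unit_interval(self, aml_inputs,
                                                         aml_labels):
        glm = FeatureLogisticClassifier(disease="AML", variant="AP")
        glm.fit(aml_inputs["AP"], aml_labels)
        p = glm.predict_proba(aml_inputs["AP"])[:, 1]
        assert np.all((p > 0) & (p < 1))

    def test_constant_feature_column_dropped_with_warning(self, aml_inputs,
                                                          aml_labels,
                                                          monkeypatch):
        import pandas as pd
        glm = FeatureLogisticClassifier(disease="AML", variant="D")
        rng = np.random.default_rng(0)
        n = len(aml_labels)
        F = pd.DataFrame({"alpha": rng.normal(size=n),
                          "n": aml_labels + rng.normal(0, 0.1, n),
                          "y0": np.full(n, 1.7)})  # constant column
        monkeypatch.setattr(
            glm, "_featurize",
            lambda X, labels=None: (F.iloc[:len(X)],
                                    (np.zeros(len(X)) if labels is None
                                     else labels),
                                    np.arange(len(X))))
        with pytest.warns(UserWarning, match="constant feature"):
            glm.fit(aml_inputs["D"], aml_labels)
        assert not glm.keep_cols_.all()
        p = glm.predict_proba(aml_inputs["D"])[:, 1]
        assert np.all((p > 0) & (p < 1))


class TestEncodeSequences:
    def test_mask_marks_exactly_the_real_points(self, aml_inputs):
        X, mask, _ = encode_sequences(aml_inputs["SN"])
        lengths = [len(i.times) for i in aml_inputs["SN"]]
        np.testing.assert_array_equal(mask.sum(axis=1), lengths)

    def test_scaling_is_invertible_on_training_fold(self, aml_inputs):
        inputs = aml_inputs["SN"]
        X, mask, (lo, hi) = encode_sequences(inputs)
        i0 = inputs[0]
        back = (X[0, :len(i0.times), 1] + 1) / 2 * (hi - lo) + lo
        np.testing.assert_allclose(back, np.log10(i0.values), rtol=1e-9)

    def test_padding_is_never_unmasked(self, aml_inputs):
        X, mask, _ = encode_sequences(aml_inputs["SN"])
        for b in range(X.shape[0]):
            L = int(mask[b].sum())
            assert np.all(mask[b, L:] == 0)
            assert np.all(X[b, L:] == 0)

    def test_empty_series_raise(self, aml_inputs):
        i0 = aml_inputs["SN"][0]
        empty = PatientInput(id="e", disease="AML", variant="SN",
                             times=np.array([]), values=np.array([]),
                             censored=np.array([], dtype=bool),
                             schedule=i0.schedule, lod=0.01)
        with pytest.raises(ValueError, match="empty"):
            encode_sequences([empty])


class TestSequenceLSTM:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        B, T, F, H = 4, 6, 3, 5
        net = BiLSTMNet(F, hidden=H, head=(4,), seed=1)
        X = rng.normal(size=(B, T, F))
        lengths = np.array([6, 3, 5, 2])
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
        y = rng.integers(0, 2, B).astype(float)
        _, grads, _ = net.loss_and_grads(X, mask, y)
        for k, v in net.params.items():
            flat = v.ravel()
            for j in rng.choice(v.size, size=min(3, v.size), replace=False):
                eps, old = 1e-6, flat[j]
                flat[j] = old + eps
                lp, _, _ = net.loss_and_grads(X, mask, y)
                flat[j] = old - eps
                lm, _, _ = net.loss_and_grads(X, mask, y)
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                assert grads[k].ravel()[j] == pytest.approx(num, abs=1e-7)

    def _toy_task(self, n=120, seed=0):
        # label is a threshold on the last observed channel-1 value
        rng = np.random.default_rng(seed)
        sch = TreatmentSchedule(disease="AML", cycles=((0.0, 7.0),))
        inputs, ys = [], []
        for i in range(n):
            L = int(rng.integers(4, 9))
            times = np.sort(rng.uniform(0.5, 8.5, L))
            vals = 10.0 ** rng.uniform(-4, 1, L)
            inputs.append(PatientInput(
                id=f"t{i}", disease="AML", variant="SN", times=times,
                values=vals, censored=np.zeros(L, dtype=bool), schedule=sch,
                lod=0.01))
            ys.append(np.log10(vals[-1]) > -1.5)
        return inputs, np.array(ys)

    def test_learns_last_value_threshold_task(self):
        inputs, y = self._toy_task()
        nn = SequenceLSTMClassifier(epochs=60, restarts=2, patience=15,
                                    random_state=0)
        nn.fit(inputs, y)
        assert nn.val_accuracy_ >= 0.9
        assert np.mean(nn.predict(inputs) == y) >= 0.9

    def test_fixed_seed_reproduces_selection_and_predictions(self):
        inputs, y = self._toy_task(n=60, seed=3)
        runs = []
        for _ in range(2):
            nn = SequenceLSTMClassifier(epochs=8, restarts=2,
                                        random_state=11)
            nn.fit(inputs, y)
            runs.append((nn.selected_run_,
                         nn.predict_proba(inputs)[:, 1]))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_probability_outputs_in_unit_interval(self):
        inputs, y = self._toy_task(n=40, seed=5)
        nn = SequenceLSTMClassifier(epochs=5, restarts=1, random_state=2)
        nn.fit(inputs, y)
        p = nn.predict_proba(inputs)[:, 1]
        assert np.all((p >= 0) & (p <= 1))


class TestPrediction:
    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            Prediction(patient_id="x", method="NN", label=True, score=1.5)
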