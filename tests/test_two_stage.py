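import numpy as np
import pandas as pd
import pytest

from conftest import fast_linear_spec, fast_rf_spec
from helpers import enumerate_cutoffs
from twostay import (
    GatedPredictions,
    PredictionPair,
    TwoStageConfig,
    customized_loss,
    fit_two_stage,
    predict_two_stage,
    sweep_regressor_threshold,
    tune_cutoff,
)
from twostay.exceptions import DegenerateTargetError, InfeasibleCutoffError
from twostay.transforms import OutcomeTransform


def _cfg(seed=0, **kw):
    kw.setdefault("classifier_spec", fast_rf_spec("classification", seed=seed))
    kw.setdefault("regressor_spec", fast_rf_spec("regression", seed=seed + 1))
    return TwoStageConfig(**kw)


class TestTuneCutoff:
    def test_separated_scores_hit_both_sensitivities(self):
        res = tune_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], target=0.99)
        assert 0.2 < res.cutoff <= 0.8
        assert res.short_sensitivity == 1.0
        assert res.prolonged_sensitivity == 1.0

    def test_all_equal_scores(self):
        # every real cutoff classifies everyone identically; the only
        # admissible rule classifies nothing prolonged
        res = tune_cutoff([0.4, 0.4, 0.4, 0.4], [0, 0, 1, 1], target=0.99)
        assert res.cutoff > 0.4
        assert res.short_sensitivity == 1.0 and res.prolonged_sensitivity == 0.0
        # ... and when scores sit at 1.0 no such cutoff exists
        with pytest.raises(InfeasibleCutoffError) as err:
            tune_cutoff([1.0, 1.0], [0, 1], target=0.99)
        assert err.value.best_attainable < 0.99

    def test_degenerate_target_zero(self):
        res = tune_cutoff([0.3, 0.5, 0.7], [0, 1, 1], target=0.0)
        assert res.prolonged_sensitivity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTargetError):
            tune_cutoff([0.1, 0.9], [1, 1], target=0.5)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            target = float(rng.choice([0.0, 0.5, 0.9, 0.99, 1.0]))
            _, best = enumerate_cutoffs(scores, labels, target)
            if best is None:
                with pytest.raises(InfeasibleCutoffError):
                    tune_cutoff(scores, labels, target)
            else:
                res = tune_cutoff(scores, labels, target)
                assert res.short_sensitivity >= target
                assert res.prolonged_sensitivity == pytest.approx(best[2])
                assert res.cutoff == pytest.approx(best[0])

    def test_prolonged_sensitivity_mode(self):
        res = tune_cutoff(
            [0.1, 0.2, 0.6, 0.9], [0, 0, 1, 1], target=1.0, mode="prolonged_sensitivity"
        )
        # the largest cutoff still catching every prolonged sample
        assert res.cutoff == pytest.approx(0.6)
        assert res.prolonged_sensitivity == 1.0


def test_config_validation():
    with pytest.raises(ValueError, match="tau_r"):
        _cfg(tau_c=7.0, tau_r=5.0)
    with pytest.raises(ValueError):
        _cfg(target_short_sensitivity=0.0)
    with pytest.raises(ValueError):
        _cfg(mode="specificity")


class TestGatedPredictions:
    def test_partition_invariant_enforced(self):
        with pytest.raises(ValueError, match="exactly one"):
            GatedPredictions(np.array([True, False]), np.array([3.0, 2.0]))
        with pytest.raises(ValueError):
            GatedPredictions(np.array([False]), np.array([-1.0]))

    def test_imputation_and_csv_round_trip(self, tmp_path):
        g = GatedPredictions(np.array([True, False]), np.array([np.nan, 2.5]))
        np.testing.assert_array_equal(g.imputed(7.0), [7.0, 2.5])
        path = tmp_path / "pred.csv"
        g.to_csv(path, row_id=[10, 11])
        text = path.read_text().splitlines()
        assert text[0] == "row_id,is_prolonged,los_estimate"
        assert text[1] == "10,True,"  # empty estimate, never a sentinel
        assert text[2] == "11,False,2.5"


class TestFitPredict:
    def test_separable_cohort_gates_perfectly(self, separable_cohort):
        # with a deterministically separable prolonged class, demanding full
        # short-class sensitivity still leaves prolonged sensitivity at 1
        table = separable_cohort.to_frame()
        y = table["los_days"].to_numpy()
        X = table.drop(columns=["los_days"])
        model = fit_two_stage(
            X.iloc[:1500], y[:1500], _cfg(seed=3, target_short_sensitivity=1.0)
        )
        gated = predict_two_stage(model, X.iloc[1500:])
        truth = y[1500:] >= 7
        np.testing.assert_array_equal(gated.is_prolonged, truth)
        assert gated.n_prolonged + np.isfinite(gated.los_estimate).sum() == gated.n

    def test_separable_customized_loss_is_short_mae_share(self, separable_cohort):
        """With a perfect gate the whole pipeline's customized loss reduces to
        the stage-2 absolute errors on truly short stays."""
        table = separable_cohort.to_frame()
        y = table["los_days"].to_numpy()
        X = table.drop(columns=["los_days"])
        model = fit_two_stage(
            X.iloc[:1500], y[:1500], _cfg(seed=4, target_short_sensitivity=1.0)
        )
        gated = model.predict(X.iloc[1500:])
        y_te = y[1500:]
        assert (gated.is_prolonged == (y_te >= 7)).all()
        loss = customized_loss(PredictionPair(y_te, gated.imputed(7.0)), 7.0)
        short = ~gated.is_prolonged
        expected = np.abs(gated.los_estimate[short] - y_te[short]).sum() / len(y_te)
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_stage2_training_set_respects_threshold(self, xy):
        X, y = xy
        cfg = _cfg(seed=5, tau_r=7.0)  # tau_r == tau_c: stage 2 sees y <= 7 only
        model = fit_two_stage(X, y, cfg)
        assert model.n_stage2_train == int((y <= 7.0).sum())
        assert model.regressor.learner.y_max <= np.log(7.0) + 1e-12  # log scale
        cfg35 = _cfg(seed=5, tau_r=35.0)
        model35 = fit_two_stage(X, y, cfg35)
        assert model35.n_stage2_train == int((y <= 35.0).sum())

    def test_oof_short_sensitivity_meets_target(self, xy):
        X, y = xy
        model = fit_two_stage(
            X, y, _cfg(seed=6, classifier_spec=fast_linear_spec("classification", seed=6))
        )
        assert model.oof_short_sensitivity >= 0.99

    def test_all_short_training_is_degenerate(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = rng.uniform(0.5, 5.0, 50)
        with pytest.raises(DegenerateTargetError):
            fit_two_stage(X, y, _cfg())

    def test_negative_outcomes_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=20)})
        with pytest.raises(ValueError, match="non-negative"):
            fit_two_stage(X, np.linspace(-1, 10, 20), _cfg())


@pytest.fixture(scope="module")
def split(default_cohort):
    table = default_cohort.to_frame()
    y = table["los_days"].to_numpy()
    X = table.drop(columns=["los_days"])
    return X.iloc[:2600], y[:2600], X.iloc[2600:], y[2600:]


class TestSweep:
    def test_single_tau_reproduces_direct_fit(self, split):
        X_tr, y_tr, X_te, y_te = split
        cfg = _cfg(seed=8, tau_r=21.0)
        table = sweep_regressor_threshold(X_tr, y_tr, X_te, y_te, cfg, [21.0])
        from dataclasses import replace

        direct = fit_two_stage(X_tr, y_tr, replace(cfg, tau_r=21.0))
        gated = direct.predict(X_te)
        pair = PredictionPair(y_te, gated.imputed(7.0))
        assert table.loc[0, "customized"] == pytest.approx(customized_loss(pair, 7.0))
        assert table.loc[0, "n_stage2_train"] == direct.n_stage2_train

    def test_sweep_reports_all_thresholds(self, split):
        X_tr, y_tr, X_te, y_te = split
        cfg = _cfg(seed=9, stage2_transform=OutcomeTransform.identity())
        table = sweep_regressor_threshold(X_tr, y_tr, X_te, y_te, cfg, [7.0, 21.0, 35.0])
        assert list(table["tau_r"]) == [7.0, 21.0, 35.0]
        assert (table["n_stage2_train"].diff().dropna() >= 0).all()
        # identity-transform forest stage 2: numeric predictions stay under tau_r
        assert (table["max_numeric_prediction"] <= table["tau_r"] + 1e-9).all()

    def test_tau_below_classifier_threshold_rejected(self, split):
        X_tr, y_tr, X_te, y_te = split
        with pytest.raises(ValueError, match=">= tau_c"):
            sweep_regressor_threshold(X_tr, y_tr, X_te, y_te, _cfg(), [3.0])
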