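import numpy as np
import pytest

from dcenms import (
    AMBundle,
    StudySamples,
    adjusted_r2,
    auc_nonparametric,
    ccf,
    ccf_stopping_epoch,
    classify_nms,
    nested_cv,
    optimize_thresholds,
    pearson_r,
    train_adaptive_bundle,
    train_mlp_lm,
)
from dcenms.adaptive_models import MLPWeights, ThresholdResult


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(y, y) == pytest.approx(1.0)
        assert adjusted_r2(y, y) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_auc_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([False, False, True, True])
        assert auc_nonparametric(scores, labels) == 1.0

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        labels = rng.random(200) > 0.6
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (pos.size * neg.size)
        assert auc_nonparametric(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=100)
        labels = rng.random(100) > 0.5
        a0 = auc_nonparametric(scores, labels)
        a1 = auc_nonparametric(np.exp(3 * scores) + 7, labels)
        assert a0 == pytest.approx(a1, abs=1e-12)

    def test_ccf(self):
        assert ccf([1, 2, 3, 1], [1, 2, 2, 1]) == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# Levenberg–Marquardt trainer
# ---------------------------------------------------------------------------

class TestTrainMlpLm:
    def test_linear_target_matches_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 4))
        # amplitudes inside the tanh near-linear range so the optimum is reachable
        w = np.array([0.1, -0.2, 0.05, 0.3])
        y = x @ w
        net, hist = train_mlp_lm(x, y, h=1, seed=0, max_epochs=300, rel_tol=1e-14)
        xa = np.column_stack([x, np.ones(80)])
        coef, *_ = np.linalg.lstsq(xa, y, rcond=None)
        mse_opt = float(np.mean((y - xa @ coef) ** 2))  # = 0 for this target
        assert hist.mse[-1] < mse_opt + 1e-6
        assert np.mean((net.predict(x) - y) ** 2) < 1e-6

    def test_constant_target(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 3))
        y = np.full(30, 2.5)
        net, hist = train_mlp_lm(x, y, h=2, seed=0, max_epochs=50)
        np.testing.assert_allclose(net.predict(x), 2.5, atol=1e-6)

    def test_xor_capacity(self):
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        x = np.tile(x, (10, 1))
        y = (x[:, 0] != x[:, 1]).astype(float)
        net, hist = train_mlp_lm(x, y, h=3, seed=1, max_epochs=200, rel_tol=1e-14)
        assert hist.mse[-1] < 1e-3

    def test_accepted_steps_never_increase_mse(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 6))
        y = np.sin(x @ rng.normal(size=6)) + 0.1 * rng.normal(size=60)
        _, hist = train_mlp_lm(x, y, h=4, seed=2, max_epochs=60)
        mse = np.array(hist.mse)
        assert np.all(np.diff(mse) <= 1e-15)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(40, 5))
        y = x[:, 0] - x[:, 1] ** 2
        n1, _ = train_mlp_lm(x, y, h=3, seed=7, max_epochs=20)
        n2, _ = train_mlp_lm(x, y, h=3, seed=7, max_epochs=20)
        assert np.array_equal(n1.pack(), n2.pack())

    def test_dual_and_primal_steps_agree(self):
        # n < p exercises the sample-space solve; compare against a wide net
        rng = np.random.default_rng(8)
        x = rng.normal(size=(25, 40))  # p = h*(40+2)+1 > n for h = 2
        y = x[:, 0] * 0.5
        net, hist = train_mlp_lm(x, y, h=2, seed=0, max_epochs=40)
        assert hist.mse[-1] < 1e-8  # interpolation regime must be reachable

    def test_sample_cap_subsamples(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(500, 3))
        y = x[:, 0]
        _, hist = train_mlp_lm(x, y, h=1, seed=0, max_epochs=5, sample_cap=100)
        assert "subsampled" in hist.stop_reason


class TestCcfStoppingEpoch:
    def test_saturating_curve(self):
        curve = 0.9 * (1 - np.exp(-np.arange(1, 51) / 8.0))
        epoch = ccf_stopping_epoch(curve)
        plateau = curve[-5:].mean()
        brute = next(i + 1 for i, v in enumerate(curve) if v >= 0.9 * plateau)
        assert epoch == brute

    def test_constant_curve_stops_immediately(self):
        assert ccf_stopping_epoch(np.full(20, 0.7)) == 1

    def test_logistic_curve_matches_direct_scan(self):
        e = np.arange(1, 101)
        curve = 1.0 / (1.0 + np.exp(-(e - 30) / 6.0))
        plateau = curve[-10:].mean()
        brute = next(i + 1 for i, v in enumerate(curve) if v >= 0.9 * plateau)
        assert ccf_stopping_epoch(curve) == brute

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            ccf_stopping_epoch([0.1, 0.2])


# ---------------------------------------------------------------------------
# thresholds and classification
# ---------------------------------------------------------------------------

def threshold_oracle(r_lo, r_hi, tolerance):
    """Exhaustive scan over the same candidate set, written independently."""
    pooled = sorted(set(list(r_lo) + list(r_hi)))
    best = None
    fallback = None
    for a, b in zip(pooled[:-1], pooled[1:]):
        cut = 0.5 * (a + b)
        e_lo = np.mean(np.asarray(r_lo) >= cut)
        e_hi = np.mean(np.asarray(r_hi) < cut)
        bal = 1 - 0.5 * (e_lo + e_hi)
        if e_lo <= tolerance and e_hi <= tolerance:
            if best is None or bal > best[1]:
                best = (cut, bal)
        key = (max(e_lo, e_hi), -bal)
        if fallback is None or key < fallback[1]:
            fallback = (cut, key)
    if best is not None:
        return best[0], True
    return fallback[0], False


class TestOptimizeThresholds:
    def test_perfect_separation_returns_gap_midpoint(self):
        resp = np.array([1.0, 1.2, 1.4, 1.6, 1.8, 2.0])
        labels = np.array([1, 1, 1, 2, 2, 2])
        out = optimize_thresholds(resp, labels)
        t = out["t12"]
        assert t.cut == pytest.approx(1.5)
        assert t.err_low == 0.0 and t.err_high == 0.0 and t.feasible

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            r1 = rng.normal(1.0, 0.3, rng.integers(10, 40))
            r2 = rng.normal(2.0, 0.4, rng.integers(10, 40))
            resp = np.concatenate([r1, r2])
            labels = np.concatenate([np.ones(r1.size, int), np.full(r2.size, 2)])
            out = optimize_thresholds(resp, labels, tolerance=0.05)["t12"]
            cut, feas = threshold_oracle(r1, r2, 0.05)
            assert out.cut == pytest.approx(cut, abs=1e-12)
            assert out.feasible == feas

    def test_huge_tolerance_reduces_to_balanced_accuracy_cut(self):
        rng = np.random.default_rng(11)
        r1 = rng.normal(0.0, 1.0, 50)
        r2 = rng.normal(1.0, 1.0, 50)
        resp = np.concatenate([r1, r2])
        labels = np.concatenate([np.ones(50, int), np.full(50, 2)])
        out = optimize_thresholds(resp, labels, tolerance=0.5)["t12"]
        cut, _ = threshold_oracle(r1, r2, 1.1)  # constraint inactive
        assert out.cut == pytest.approx(cut, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_thresholds(np.array([1.0, 1.1]), np.array([1, 1]))


class TestClassifyNms:
    # decision rule exercised at the published working points 1.73/1.92/2.44
    WORKING = {
        "t12": ThresholdResult(1.73, 0, 0, True),
        "t13": ThresholdResult(1.92, 0, 0, True),
        "t23": ThresholdResult(2.44, 0, 0, True),
    }

    @pytest.mark.parametrize("resp,label", [(1.0, 1), (2.0, 2), (3.0, 3)])
    def test_interval_membership(self, resp, label):
        assert classify_nms(resp, self.WORKING) == label

    def test_boundary_is_right_closed(self):
        assert classify_nms(1.73, self.WORKING) == 2
        assert classify_nms(2.44, self.WORKING) == 3


# ---------------------------------------------------------------------------
# bundle training and nested CV (tiny synthetic cohort)
# ---------------------------------------------------------------------------

def synthetic_cohort(n_studies=10, n_vox=60, d=12, seed=0, study_effect=0.0):
    rng = np.random.default_rng(seed)
    w_lab = rng.normal(size=d)
    w_vp = rng.normal(size=d)
    studies = []
    for i in range(n_studies):
        x = rng.normal(size=(n_vox, d))
        score = x @ w_lab
        labels = np.digitize(score, np.quantile(score, [0.5, 0.8])) + 1
        vp = 0.02 + 0.005 * np.tanh(x @ w_vp) + study_effect * rng.normal()
        ktrans = np.where(labels >= 2, 0.02 + 0.005 * np.tanh(x @ w_vp[::-1]), np.nan)
        ve = np.where(labels == 3, 0.1 + 0.05 * np.tanh(x[:, 0]), np.nan)
        studies.append(StudySamples(
            study_id=f"s{i}", x=x, nms_labels=labels,
            pk={"vp": vp, "ktrans": ktrans, "ve": ve},
        ))
    return studies


class TestBundle:
    def test_bundle_deterministic_and_serializable(self):
        st = synthetic_cohort(2, 80, seed=3)
        x = np.concatenate([s.x for s in st])
        lab = np.concatenate([s.nms_labels for s in st])
        pk = {k: np.concatenate([s.pk[k] for s in st]) for k in ("vp", "ktrans", "ve")}
        b1 = train_adaptive_bundle(x, lab, pk, seed=5, h_nms=3, h_pk=2, max_epochs=10)
        b2 = train_adaptive_bundle(x, lab, pk, seed=5, h_nms=3, h_pk=2, max_epochs=10)
        assert b1.to_json() == b2.to_json()
        restored = AMBundle.from_json(b1.to_json())
        np.testing.assert_array_equal(restored.nms_net.w1, b1.nms_net.w1)
        np.testing.assert_array_equal(
            restored.predict_labels(x), b1.predict_labels(x))

    def test_empty_stratum_leaves_net_absent(self):
        st = synthetic_cohort(2, 60, seed=4)
        x = np.concatenate([s.x for s in st])
        lab = np.concatenate([s.nms_labels for s in st])
        pk = {k: np.concatenate([s.pk[k] for s in st]) for k in ("vp", "ktrans", "ve")}
        pk["ve"] = np.full_like(pk["ve"], np.nan)  # no usable ve targets
        b = train_adaptive_bundle(x, lab, pk, seed=0, h_nms=3, h_pk=2, max_epochs=5)
        assert b.pk_nets["ve"] is None
        assert "ve" in b.provenance["missing_nets"]

    def test_prediction_masking_follows_labels(self):
        st = synthetic_cohort(2, 80, seed=6)
        x = np.concatenate([s.x for s in st])
        lab = np.concatenate([s.nms_labels for s in st])
        pk = {k: np.concatenate([s.pk[k] for s in st]) for k in ("vp", "ktrans", "ve")}
        b = train_adaptive_bundle(x, lab, pk, seed=1, h_nms=3, h_pk=2, max_epochs=10)
        labels = b.predict_labels(x)
        preds = b.predict_params(x, labels=labels)
        assert np.all(np.isnan(preds["ktrans"][labels == 1]))
        assert np.all(np.isnan(preds["ve"][labels <= 2]))


class TestNestedCV:
    def test_outer_folds_partition_studies(self):
        studies = synthetic_cohort(10, 40, seed=7)
        rep = nested_cv(studies, k_outer=10, seed=1, hidden_grid=(2,),
                        inner_k=2, inner_repeats=1, max_epochs=6)
        assign = rep.fold_assignment
        assert sorted(assign.keys()) == sorted(s.study_id for s in studies)
        assert len(set(assign.values())) == 10  # leave-one-study-out
        assert len(rep.folds) == 10

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            nested_cv(synthetic_cohort(4, 20), k_outer=10)

    def test_deliberate_leak_inflates_outer_correlation(self):
        studies = synthetic_cohort(8, 50, seed=8, study_effect=0.02)
        kw = dict(k_outer=4, seed=2, hidden_grid=(3,), inner_k=2,
                  inner_repeats=1, max_epochs=12)
        fair = nested_cv(studies, **kw)
        leaky = nested_cv(studies, _inject_leak=True, **kw)
        assert leaky.aggregate["mean_r_vp"] > fair.aggregate["mean_r_vp"]
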