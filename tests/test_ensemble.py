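"""Splitting, candidate training, admission gates, ensemble, AD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cosolv as cv
from cosolv.ensemble import (EnsembleBuildError, SplitError, load_model,
                             save_model)
from cosolv.synth import make_descriptor_table


def small_pool(seeds=(0, 1, 2), hidden=(16, 24)):
    return [cv.NetworkConfig(hidden_units=h, seed=s)
            for h in hidden for s in seeds]


@pytest.fixture(scope="module")
def trained_ensemble():
    x, y = make_descriptor_table(600, "smooth", noise_sd=0.03, seed=42)
    return cv.build_ensemble(small_pool(), x, y, split_seed=42), x, y


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (100, (70, 15, 15)), (101, (71, 15, 15)), (20, (14, 3, 3))])
    def test_split_sizes(self, n, expected):
        tr, te, va = cv.split_dataset(n, seed=0)
        assert (len(tr), len(te), len(va)) == expected

    def test_partition_disjoint_and_complete(self):
        tr, te, va = cv.split_dataset(97, seed=5)
        allidx = np.concatenate([tr, te, va])
        assert sorted(allidx) == list(range(97))

    def test_determinism(self):
        a = cv.split_dataset(100, seed=9)
        b = cv.split_dataset(100, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_too_small_errors(self):
        with pytest.raises(SplitError):
            cv.split_dataset(10, seed=0)


class TestTrainCandidate:
    def test_constant_target_learned(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (80, 8))
        y = np.full(80, -2.0)
        net = cv.train_candidate(cv.NetworkConfig(hidden_units=4, seed=0),
                                 x[:60], y[:60], x[60:], y[60:])
        assert np.sqrt(np.mean((net.predict(x) - y) ** 2)) < 0.01

    def test_linear_target_reaches_noise_floor(self):
        x, y = make_descriptor_table(300, "linear", noise_sd=0.0, seed=1)
        tr, te, va = cv.split_dataset(300, seed=1)
        net = cv.train_candidate(cv.NetworkConfig(hidden_units=16, seed=1),
                                 x[tr], y[tr], x[te], y[te])
        rmsd_val = np.sqrt(np.mean((net.predict(x[va]) - y[va]) ** 2))
        assert rmsd_val < 0.05

    def test_same_config_is_bit_identical(self):
        x, y = make_descriptor_table(120, "smooth", noise_sd=0.02, seed=3)
        cfg = cv.NetworkConfig(hidden_units=8, seed=7, max_epochs=50)
        a = cv.train_candidate(cfg, x[:90], y[:90], x[90:], y[90:])
        b = cv.train_candidate(cfg, x[:90], y[:90], x[90:], y[90:])
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)


class FakeNet:
    """Deterministic stand-in emitting preset predictions."""

    def __init__(self, preds, config=None):
        self.preds = np.asarray(preds, float)
        self.config = config or cv.NetworkConfig()

    def predict(self, x):
        return self.preds[:len(np.atleast_2d(x))]


class TestAdmissionGates:
    """The gate is the exact three-way conjunction."""

    def _member(self, rmsd_target, outlier_pct, reliability_pct, n=200):
        # construct residuals achieving the requested statistics
        rng = np.random.default_rng(0)
        y = np.full(n, -2.0)
        n_out = int(round(outlier_pct / 100 * n))
        base = np.where(np.arange(n) % 2 == 0, 1.0, -1.0) * 0.5
        resid = base.copy()
        resid[:n_out] = 40.0  # gross outliers, > 3 sd
        resid *= rmsd_target / np.sqrt(np.mean(resid ** 2))
        pred = y + resid
        n_bad = int(round((100 - reliability_pct) / 100 * n))
        pred[-n_bad:] = 0.5 if n_bad else pred[-n_bad:]  # log10 x > 0
        return FakeNet(pred), y

    def test_rmsd_gate(self):
        net, y = self._member(0.07, 0.0, 100.0)
        rep = cv.evaluate_member(net, np.zeros((len(y), 8)), y)
        assert rep.rmsd_val == pytest.approx(0.07, abs=1e-6)
        assert not rep.admitted

    def test_outlier_gate(self):
        net, y = self._member(0.05, 3.0, 100.0)
        rep = cv.evaluate_member(net, np.zeros((len(y), 8)), y)
        assert rep.outlier_rate == pytest.approx(3.0, abs=0.01)
        assert not rep.admitted

    def test_reliability_gate(self):
        net, y = self._member(0.05, 0.0, 98.0)
        rep = cv.evaluate_member(net, np.zeros((len(y), 8)), y)
        assert rep.reliability_rate == pytest.approx(98.0, abs=0.01)
        assert not rep.admitted

    def test_compliant_member_admitted(self):
        net, y = self._member(0.05, 1.0, 100.0)
        rep = cv.evaluate_member(net, np.zeros((len(y), 8)), y)
        assert rep.rmsd_val < 0.06 and rep.outlier_rate <= 2.0
        assert rep.admitted

    def test_perfect_predictor_admitted(self):
        y = np.linspace(-4, -1, 50)
        rep = cv.evaluate_member(FakeNet(y), np.zeros((50, 8)), y)
        assert rep.rmsd_val == 0.0 and rep.outlier_rate == 0.0
        assert rep.admitted

    @given(st.floats(0.01, 0.12), st.floats(0, 5), st.floats(95, 100))
    @settings(max_examples=30, deadline=None)
    def test_admission_is_exact_conjunction(self, rmsd_t, outl, rel):
        net, y = self._member(rmsd_t, outl, rel, n=1000)
        rep = cv.evaluate_member(net, np.zeros((len(y), 8)), y)
        expected = (rep.rmsd_val < 0.06 and rep.outlier_rate <= 2.0
                    and rep.reliability_rate >= 99.0)
        assert rep.admitted == expected


class TestEnsemble:
    def test_noise_floor_problem_admits_members(self, trained_ensemble):
        model, _, _ = trained_ensemble
        assert len(model.members) >= 1
        admitted = [r for r in model.reports if r.admitted]
        assert all(r.rmsd_val < 0.06 for r in admitted)

    def test_prediction_within_member_extremes(self, trained_ensemble):
        model, x, _ = trained_ensemble
        q = np.random.default_rng(1).uniform(0, 1, (20, 8))
        preds = model.member_predictions(q)
        ens = np.atleast_1d(model.predict(q))
        assert np.all(ens <= preds.max(axis=0) + 1e-12)
        assert np.all(ens >= preds.min(axis=0) - 1e-12)

    def test_ensemble_beats_median_member(self):
        x, y = make_descriptor_table(600, "smooth", noise_sd=0.03, seed=11)
        model = cv.build_ensemble(small_pool(), x, y, split_seed=11)
        _, _, va = cv.split_dataset(len(x), 11)
        ens_rmsd = np.sqrt(np.mean((np.atleast_1d(model.predict(x[va]))
                                    - y[va]) ** 2))
        member_rmsds = [np.sqrt(np.mean(
            (m.predict(model._normalize(x[va])) - y[va]) ** 2))
            for m in model.members]
        assert ens_rmsd <= np.median(member_rmsds) + 1e-9

    def test_build_is_deterministic(self):
        x, y = make_descriptor_table(200, "smooth", noise_sd=0.03, seed=2)
        pool = small_pool(seeds=(0,), hidden=(16,))
        # relaxed gates: this checks bit-identical training, not accuracy
        thr = cv.AdmissionThresholds(rmsd_max=1.0)
        a = cv.build_ensemble(pool, x, y, split_seed=2, thresholds=thr)
        b = cv.build_ensemble(pool, x, y, split_seed=2, thresholds=thr)
        assert len(a.members) == len(b.members)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.w1, mb.w1)

    def test_empty_admission_raises_with_diagnostics(self):
        x, y = make_descriptor_table(200, "smooth", noise_sd=0.5, seed=4)
        pool = [cv.NetworkConfig(hidden_units=4, seed=0, max_epochs=10)]
        with pytest.raises(EnsembleBuildError, match="rmsd"):
            cv.build_ensemble(pool, x, y, split_seed=4)

    def test_round_trip_serialization(self, trained_ensemble, tmp_path):
        model, x, _ = trained_ensemble
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        q = x[:7]
        assert np.allclose(np.atleast_1d(model.predict(q)),
                           np.atleast_1d(back.predict(q)), atol=0)


class TestApplicabilityDomain:
    def test_training_point_in_domain(self, trained_ensemble):
        model, x, _ = trained_ensemble
        tr, _, _ = cv.split_dataset(len(x), 42)
        inside = sum(cv.applicability_domain(model, x[i])[0]
                     for i in tr[:50])
        assert inside >= 45  # leverage cutoff trims only extreme points

    def test_far_query_out_of_domain(self, trained_ensemble):
        model, x, _ = trained_ensemble
        q = x[0].copy()
        q[3] = x[:, 3].max() * 10 + 5
        ok, diag = cv.applicability_domain(model, q)
        assert not ok and not diag["in_box"]

    def test_mean_training_leverage_is_hat_trace(self, trained_ensemble):
        # trace of the hat matrix equals p+1, so leverages average (p+1)/n
        model, x, _ = trained_ensemble
        tr, _, _ = cv.split_dataset(len(x), 42)
        levs = [cv.applicability_domain(model, x[i])[1]["leverage"]
                for i in tr]
        assert np.mean(levs) == pytest.approx((8 + 1) / len(tr), rel=1e-9)
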