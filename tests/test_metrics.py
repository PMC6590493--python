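"""Agreement metrics against exhaustive-pair and ANOVA oracles."""

import numpy as np
import pytest
import scipy.stats

from cellquant.errors import UndefinedMetricError, UnstableCIError
from cellquant.metrics import (
    agreement_report,
    bootstrap_ci,
    icc_a1,
    kendall_tau_b,
    prediction_probability,
)


def _pair_oracle(x, y):
    """Pure-python exhaustive pair classification."""
    nc = nd = tx = ty = txy = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                txy += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    return nc, nd, tx, ty, txy


def _tau_b_oracle(x, y):
    nc, nd, tx, ty, txy = _pair_oracle(x, y)
    npairs = len(x) * (len(x) - 1) // 2
    return (nc - nd) / np.sqrt((npairs - tx - txy) * (npairs - ty - txy))


def _p_k_oracle(x, y):
    nc, nd, tx, _, _ = _pair_oracle(x, y)
    return (nc + tx / 2) / (nc + nd + tx)


def _icc_oracle(x, y):
    """ICC(A,1) from explicitly enumerated ANOVA sums (k = 2)."""
    n = len(x)
    data = np.array([x, y], dtype=float).T
    grand = data.sum() / (2 * n)
    msr = 2 * sum((row.mean() - grand) ** 2 for row in data) / (n - 1)
    msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(2)) / 1
    sse = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(2)
    )
    mse = sse / (n - 1)
    return (msr - mse) / (msr + mse + (2 / n) * (msc - mse))


def _tied_instance(rng, n):
    x = rng.integers(0, 6, size=n).astype(float)
    y = np.clip(x + rng.integers(-2, 3, size=n), 0, 6)
    return x, y


class TestKendallTauB:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert kendall_tau_b(x, x) == 1.0

    def test_perfect_reversal(self):
        x = np.arange(10.0)
        assert kendall_tau_b(x, x[::-1]) == -1.0

    def test_worked_tie_example(self):
        # n_c=1, n_d=0, n_Tx=1, n_Ty=1, n_Txy=0 -> 1/sqrt(2*2)
        assert kendall_tau_b([1, 1, 2], [1, 2, 2]) == pytest.approx(0.5)

    def test_matches_exhaustive_oracle_on_tied_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            x, y = _tied_instance(rng, n)
            try:
                got = kendall_tau_b(x, y)
            except UndefinedMetricError:
                assert len(set(x)) == 1 or len(set(y)) == 1
                continue
            assert got == pytest.approx(_tau_b_oracle(x, y), abs=1e-12)

    def test_matches_scipy(self, rng):
        x, y = _tied_instance(rng, 80)
        expected = scipy.stats.kendalltau(x, y, variant="b").statistic
        assert kendall_tau_b(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self, rng):
        x, y = _tied_instance(rng, 40)
        assert kendall_tau_b(x, y) == pytest.approx(kendall_tau_b(y, x))

    def test_invariant_under_monotone_transform(self, rng):
        x, y = _tied_instance(rng, 40)
        assert kendall_tau_b(np.exp(x), y**3 + y) == pytest.approx(
            kendall_tau_b(x, y)
        )

    def test_all_tied_undefined(self):
        with pytest.raises(UndefinedMetricError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])


class TestPredictionProbability:
    def test_perfect_concordance(self):
        x = np.arange(8.0)
        assert prediction_probability(x, 2 * x) == 1.0

    def test_constant_estimate_gives_half(self):
        assert prediction_probability([3, 3, 3, 3], [1, 2, 3, 4]) == 0.5

    def test_worked_tie_example(self):
        assert prediction_probability([1, 1, 2], [1, 2, 2]) == pytest.approx(0.75)

    def test_matches_exhaustive_oracle_on_tied_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            x, y = _tied_instance(rng, n)
            try:
                got = prediction_probability(x, y)
            except UndefinedMetricError:
                continue
            assert got == pytest.approx(_p_k_oracle(x, y), abs=1e-12)

    def test_not_symmetric_when_ties_differ(self):
        # Ties in the estimate earn half credit; ties in the reference
        # remove the pair, so swapping the roles changes the value.
        x, y = [1, 2, 3], [1, 1, 2]
        assert prediction_probability(x, y) == pytest.approx(1.0)
        assert prediction_probability(y, x) == pytest.approx(5 / 6)

    def test_invariant_under_monotone_transform(self, rng):
        x, y = _tied_instance(rng, 40)
        assert prediction_probability(2 * x + 1, np.sqrt(y + 1)) == pytest.approx(
            prediction_probability(x, y)
        )


class TestIcc:
    def test_identical_measurements(self):
        assert icc_a1([1, 2, 3.0], [1, 2, 3.0]) == pytest.approx(1.0)

    def test_shifted_measurements_below_one(self):
        x, y = [1, 2, 3.0], [1.1, 2.1, 3.1]
        got = icc_a1(x, y)
        assert got < 1.0
        assert got == pytest.approx(_icc_oracle(x, y), abs=1e-12)

    def test_reversed_measurements_negative(self):
        x, y = [1, 2, 3, 4.0], [4, 3, 2, 1.0]
        got = icc_a1(x, y)
        assert got < 0
        assert got == pytest.approx(_icc_oracle(x, y), abs=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = x + rng.normal(0, 0.5, size=n)
            assert icc_a1(x, y) == pytest.approx(_icc_oracle(x, y), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.3, size=30)
        df = pd.DataFrame(
            {
                "target": np.repeat(np.arange(30), 2),
                "rater": ["a", "b"] * 30,
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            df, targets="target", raters="rater", ratings="score"
        )
        expected = table.loc[
            table["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"
        ].item()
        assert icc_a1(x, y) == pytest.approx(expected, abs=1e-8)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            icc_a1([2, 2, 2.0], [2, 2, 2.0])


class TestBootstrap:
    def test_perfect_agreement_collapses_interval(self, rng):
        x = rng.normal(size=50)
        lo, hi = bootstrap_ci(kendall_tau_b, x, x, replicates=200, seed=0)
        assert lo == hi == 1.0

    def test_same_seed_identical_interval(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0, 1, 40)
        a = bootstrap_ci(kendall_tau_b, x, y, replicates=300, seed=9)
        b = bootstrap_ci(kendall_tau_b, x, y, replicates=300, seed=9)
        assert a == b

    def test_interval_contains_point_estimate(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(0, 0.5, 60)
        lo, hi = bootstrap_ci(kendall_tau_b, x, y, replicates=2000, seed=1)
        assert lo <= kendall_tau_b(x, y) <= hi

    def test_mostly_degenerate_resamples_unstable(self):
        # x and y each carry their variation in a single sample, so most
        # resamples are all-tied in one of the two variables.
        x = np.array([1.0] * 29 + [2.0])
        y = np.array([5.0] + [1.0] * 29)
        with pytest.raises(UnstableCIError):
            bootstrap_ci(kendall_tau_b, x, y, replicates=200, seed=0)


class TestAgreementReport:
    def test_report_fields_and_ci_ordering(self, rng):
        x = rng.uniform(size=60)
        y = np.clip(x + rng.normal(0, 0.1, 60), 0, 1)
        rep = agreement_report(x, y, replicates=300, seed=0)
        assert rep.n == 60
        assert -1 <= rep.tau_b <= 1 and 0 <= rep.p_k <= 1 and rep.icc <= 1
        for name in ("icc", "tau_b", "p_k"):
            lo, hi = rep.ci[name]
            assert lo <= getattr(rep, name) <= hi

    def test_round_trips_to_json(self, rng, tmp_path):
        import json

        x = rng.uniform(size=30)
        rep = agreement_report(x, x + 0.01, replicates=0)
        rep.to_json(tmp_path / "r.json")
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["n"] == 30 and "tau_b" in loaded
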