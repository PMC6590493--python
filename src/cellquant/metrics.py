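"""Agreement statistics between automated and reference cellularity.

Three metrics quantify how well an automated estimate x agrees with a
reference measurement y over n samples:

* ``icc_a1`` — intraclass correlation ICC(A,1): two-way ANOVA (rows =
  samples, columns = the two measurements), absolute agreement, single
  measurement:

      ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),  k = 2.

* ``kendall_tau_b`` — rank correlation adjusted for ties:

      tau_b = (n_c - n_d) / sqrt((n_p - n_Tx - n_Txy)(n_p - n_Ty - n_Txy))

  with n_p = n(n-1)/2 total pairs, n_c / n_d concordant / discordant
  pairs, n_Tx ties only in x, n_Ty only in y, n_Txy in both.

* ``prediction_probability`` — the concordance-style P_K statistic

      P_K = (n_c + n_Tx / 2) / (n_c + n_d + n_Tx),

  which excludes pairs tied in the reference and credits half for ties in
  the estimate; unlike tau-b it is not symmetric in its arguments.

Pair counts are exact (full pair classification, no normal approximation).
Confidence intervals are nonparametric percentile bootstrap over samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError, UnstableCIError


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    return x, y


def icc_a1(x, y) -> float:
    """ICC(A,1): two-way ANOVA absolute agreement between two measurements."""
    x, y = _as_pair(x, y)
    n = x.size
    if n < 3:
        raise InvalidInputError("ICC needs at least 3 samples")
    data = np.stack([x, y], axis=1)  # rows = samples, columns = measurements
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = np.sum((data - grand) ** 2)
    if ss_total == 0:
        raise UndefinedMetricError("zero total variance: ICC undefined")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise UndefinedMetricError("degenerate ANOVA layout: ICC undefined")
    return float((ms_r - ms_e) / denom)


def _pair_counts(x: np.ndarray, y: np.ndarray) -> dict[str, int]:
    """Exact classification of all sample pairs (vectorized O(n^2))."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    dx, dy = dx[iu], dy[iu]
    tie_x, tie_y = dx == 0, dy == 0
    return {
        "n_pairs": dx.size,
        "concordant": int(np.sum((dx * dy) > 0)),
        "discordant": int(np.sum((dx * dy) < 0)),
        "ties_x_only": int(np.sum(tie_x & ~tie_y)),
        "ties_y_only": int(np.sum(tie_y & ~tie_x)),
        "ties_both": int(np.sum(tie_x & tie_y)),
    }


def kendall_tau_b(x, y) -> float:
    x, y = _as_pair(x, y)
    if x.size < 2:
        raise InvalidInputError("tau-b needs at least 2 samples")
    c = _pair_counts(x, y)
    dx = c["n_pairs"] - c["ties_x_only"] - c["ties_both"]
    dy = c["n_pairs"] - c["ties_y_only"] - c["ties_both"]
    if dx == 0 or dy == 0:
        raise UndefinedMetricError("all values tied in one argument")
    return float((c["concordant"] - c["discordant"]) / np.sqrt(dx * dy))


def prediction_probability(x, y) -> float:
    """P_K with x the automated estimate and y the reference."""
    x, y = _as_pair(x, y)
    if x.size < 2:
        raise InvalidInputError("P_K needs at least 2 samples")
    c = _pair_counts(x, y)
    denom = c["concordant"] + c["discordant"] + c["ties_x_only"]
    if denom == 0:
        raise UndefinedMetricError("no pairs with distinct reference values")
    return float((c["concordant"] + c["ties_x_only"] / 2) / denom)


def bootstrap_ci(
    metric,
    x,
    y,
    replicates: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile 95% bootstrap interval of ``metric(x, y)`` over samples.

    Resamples (x_i, y_i) pairs with replacement; resamples on which the
    metric is undefined are skipped and counted, and more than 50%
    degenerate resamples raise :class:`UnstableCIError`.
    """
    x, y = _as_pair(x, y)
    if replicates < 100:
        raise InvalidInputError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    values = []
    degenerate = 0
    for _ in range(replicates):
        idx = rng.integers(0, x.size, size=x.size)
        try:
            values.append(metric(x[idx], y[idx]))
        except UndefinedMetricError:
            degenerate += 1
    if degenerate > replicates // 2:
        raise UnstableCIError(
            f"{degenerate}/{replicates} bootstrap resamples were degenerate"
        )
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class AgreementReport:
    """ICC, tau-b and P_K with bootstrap CIs for one (estimate, reference) pairing."""

    icc: float
    tau_b: float
    p_k: float
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_replicates: int = 0
    bootstrap_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "icc": self.icc,
            "tau_b": self.tau_b,
            "p_k": self.p_k,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "bootstrap": {
                "replicates": self.bootstrap_replicates,
                "seed": self.bootstrap_seed,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def agreement_report(
    estimate,
    reference,
    replicates: int = 2000,
    seed: int | None = None,
) -> AgreementReport:
    """Compute all three agreement metrics, with CIs when replicates > 0."""
    x, y = _as_pair(estimate, reference)
    report = AgreementReport(
        icc=icc_a1(x, y),
        tau_b=kendall_tau_b(x, y),
        p_k=prediction_probability(x, y),
        n=x.size,
        bootstrap_replicates=replicates,
        bootstrap_seed=seed,
    )
    if replicates:
        for name, fn in (
            ("icc", icc_a1),
            ("tau_b", kendall_tau_b),
            ("p_k", prediction_probability),
        ):
            report.ci[name] = bootstrap_ci(fn, x, y, replicates, seed)
    return report
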