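"""Statistical gating that reduces the 20 normalization methods to a retained set.

Each normalized dataset is flattened to one value vector, paired by
(audiogram index, frequency index) — m = n_audiograms × 8 — and compared
against a reference method (z-score by default) with three tests:

1. **Paired t-test** on the mean difference.  A method whose mean does not
   differ from the reference (p > α) adds no new information and is removed
   as redundant.
2. **F-test** on the variance ratio (larger sample variance over smaller).
   A method whose variability equals the reference's is likewise removed.
3. **Correlation t-test** on Pearson r.  Only methods significantly and
   *positively* correlated with the reference are retained: positive
   correlation means the relative levels — the audiogram shapes — survived
   the transform.  (The significance test itself is two-sided; a transform
   with significant negative correlation mirrors every audiogram upside
   down, which defeats the gate's purpose, so the gate additionally
   requires r > 0.)

The statistics are computed from their textbook formulas; the test suite
cross-checks them against scipy's implementations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "SelectionReport",
    "paired_t_test",
    "correlation_t_test",
    "f_variance_test",
    "select_normalizations",
]

REJECT = "reject_H0"
FAIL = "fail_to_reject"


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one two-sample statistical test."""

    method_a: str
    method_b: str
    test: str  # "paired_t" | "correlation_t" | "f_variance"
    statistic: float
    df: tuple  # (df,) for t-tests, (df_num, df_den) for the F-test
    p_value: float
    decision: str  # REJECT or FAIL
    alpha: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.decision not in (REJECT, FAIL):
            raise ValueError(f"bad decision {self.decision!r}")


def paired_t_test(
    x_a: Sequence[float],
    x_b: Sequence[float],
    alpha: float = 0.05,
    method_a: str = "A",
    method_b: str = "B",
) -> PairedTestResult:
    """Two-sided paired t-test of H0: mean difference = 0.

    t = D̄ / (S_D/√m) with D_i = x_a,i − x_b,i, sample std S_D, m − 1 degrees
    of freedom.  Degenerate cases: identical vectors give p = 1
    (fail to reject); a constant nonzero shift (S_D = 0, D̄ ≠ 0) gives p = 0
    (reject) — the limit of the statistic.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test requires two 1-d vectors of equal length")
    m = a.size
    if m < 2:
        raise ValueError("paired t-test requires m >= 2")
    d = a - b
    d_bar = d.mean()
    s_d = d.std(ddof=1)
    if s_d == 0.0:
        if d_bar == 0.0:
            stat, p = 0.0, 1.0
        else:
            stat = np.inf if d_bar > 0 else -np.inf
            p = 0.0
    else:
        stat = d_bar / (s_d / np.sqrt(m))
        p = 2.0 * sps.t.sf(abs(stat), df=m - 1)
    return PairedTestResult(
        method_a=method_a, method_b=method_b, test="paired_t",
        statistic=float(stat), df=(m - 1,), p_value=float(p),
        decision=REJECT if p < alpha else FAIL, alpha=alpha,
        extra={"mean_difference": float(d_bar), "sd_difference": float(s_d)},
    )


def correlation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    method_a: str = "A",
    method_b: str = "B",
) -> PairedTestResult:
    """Two-sided t-test of H0: ρ = 0 for the Pearson correlation of x and y.

    r = cov(X, Y)/(S_X S_Y); t = r·√((m − 2)/(1 − r²)) with m − 2 degrees of
    freedom.  Perfect correlation (|r| = 1) gives p = 0.  Rejection (p < α)
    means *significant* correlation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("correlation test requires two 1-d vectors of equal length")
    m = xv.size
    if m < 3:
        raise ValueError("correlation test requires m >= 3")
    sx = xv.std(ddof=1)
    sy = yv.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        which = "x" if sx == 0.0 else "y"
        raise ValueError(f"correlation undefined: zero variance in {which}")
    cov = np.sum((xv - xv.mean()) * (yv - yv.mean())) / (m - 1)
    r = cov / (sx * sy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        stat = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        stat = r / np.sqrt((1.0 - r**2) / (m - 2))
        p = 2.0 * sps.t.sf(abs(stat), df=m - 2)
    return PairedTestResult(
        method_a=method_a, method_b=method_b, test="correlation_t",
        statistic=float(stat), df=(m - 2,), p_value=float(p),
        decision=REJECT if p < alpha else FAIL, alpha=alpha,
        extra={"r": r},
    )


def f_variance_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    method_a: str = "A",
    method_b: str = "B",
) -> PairedTestResult:
    """F-test of H0: equal variances, F = larger/smaller sample variance.

    Reject when F exceeds the upper α/2 critical value of the F distribution
    with degrees of freedom ordered to match numerator and denominator.
    Both variances zero is a degenerate equal-variance result (p = 1).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.ndim != 1 or yv.ndim != 1 or xv.size < 2 or yv.size < 2:
        raise ValueError("F-test requires two 1-d samples of size >= 2")
    v1 = xv.var(ddof=1)
    v2 = yv.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        return PairedTestResult(
            method_a=method_a, method_b=method_b, test="f_variance",
            statistic=1.0, df=(xv.size - 1, yv.size - 1), p_value=1.0,
            decision=FAIL, alpha=alpha,
            extra={"var_a": 0.0, "var_b": 0.0, "critical": float("nan")},
        )
    # numerator = the sample with the larger variance
    if v1 >= v2:
        f_stat = np.inf if v2 == 0.0 else v1 / v2
        df = (xv.size - 1, yv.size - 1)
    else:
        f_stat = np.inf if v1 == 0.0 else v2 / v1
        df = (yv.size - 1, xv.size - 1)
    critical = float(sps.f.isf(alpha / 2.0, *df))
    if np.isfinite(f_stat):
        p = 2.0 * min(float(sps.f.sf(f_stat, *df)), float(sps.f.cdf(f_stat, *df)))
    else:
        p = 0.0
    p = min(p, 1.0)
    return PairedTestResult(
        method_a=method_a, method_b=method_b, test="f_variance",
        statistic=float(f_stat), df=df, p_value=float(p),
        decision=REJECT if f_stat > critical else FAIL, alpha=alpha,
        extra={"var_a": float(v1), "var_b": float(v2), "critical": critical},
    )


@dataclass
class SelectionReport:
    """Result of the three-gate normalization-method selection."""

    reference: str
    removed_by_mean_test: list
    removed_by_variance_test: list
    removed_by_correlation_test: list
    retained: list
    all_pairwise: list  # every C(n,2) paired-t result
    gate_results: dict = field(default_factory=dict)  # method -> list of PairedTestResult

    def to_dict(self) -> dict:
        def res(t: PairedTestResult) -> dict:
            return {
                "method_a": t.method_a, "method_b": t.method_b, "test": t.test,
                "statistic": t.statistic, "df": list(t.df), "p_value": t.p_value,
                "decision": t.decision,
            }

        return {
            "reference": self.reference,
            "removed_by_mean_test": self.removed_by_mean_test,
            "removed_by_variance_test": self.removed_by_variance_test,
            "removed_by_correlation_test": self.removed_by_correlation_test,
            "retained": self.retained,
            "n_pairwise": len(self.all_pairwise),
            "all_pairwise": [res(t) for t in self.all_pairwise],
            "gate_results": {m: [res(t) for t in ts] for m, ts in self.gate_results.items()},
        }


def _flatten(dataset) -> np.ndarray:
    """One value vector per dataset, paired by (audiogram index, frequency index)."""
    return np.concatenate([a.levels for a in dataset.audiograms])


def select_normalizations(
    datasets: Sequence,
    reference: str = "z_score",
    alpha: float = 0.05,
    gate_order: Sequence[str] = ("mean", "variance", "correlation"),
) -> SelectionReport:
    """Run the three-gate selection flow over normalized datasets.

    ``datasets`` are :class:`~audioshape.normalization.NormalizedDataset`
    objects of identical cardinality.  Every method is compared against the
    single ``reference`` method (which always survives); all pairwise paired-t
    results — C(n, 2) of them — are recorded for transparency.

    Gates (default order: mean, variance, correlation):

    - ``mean``: remove methods whose paired t-test vs the reference fails to
      reject (p > α — same mean, redundant);
    - ``variance``: remove methods whose F-test vs the reference fails to
      reject (same variability, redundant);
    - ``correlation``: retain only methods significantly positively
      correlated with the reference (shape maintained).
    """
    names = [d.method_name for d in datasets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate method names in datasets")
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among dataset methods {names}")
    sizes = {len(d.audiograms) for d in datasets}
    if len(sizes) != 1:
        raise ValueError(f"datasets have differing cardinalities: {sorted(sizes)}")
    known_gates = {"mean", "variance", "correlation"}
    if set(gate_order) != known_gates:
        raise ValueError(f"gate_order must be a permutation of {sorted(known_gates)}")

    vectors = {d.method_name: _flatten(d) for d in datasets}
    ref_vec = vectors[reference]

    all_pairwise = []
    for na, nb in itertools.combinations(names, 2):
        try:
            all_pairwise.append(
                paired_t_test(vectors[na], vectors[nb], alpha=alpha, method_a=na, method_b=nb)
            )
        except ValueError as exc:
            raise ValueError(f"paired t-test failed for pair ({na}, {nb}): {exc}") from exc

    removed = {"mean": [], "variance": [], "correlation": []}
    gate_results = {m: [] for m in names}
    candidates = [n for n in names if n != reference]
    for gate in gate_order:
        survivors = []
        for name in candidates:
            try:
                if gate == "mean":
                    res = paired_t_test(vectors[name], ref_vec, alpha=alpha,
                                        method_a=name, method_b=reference)
                    keep = res.decision == REJECT  # distinct mean -> informative
                elif gate == "variance":
                    res = f_variance_test(vectors[name], ref_vec, alpha=alpha,
                                          method_a=name, method_b=reference)
                    keep = res.decision == REJECT  # distinct variability
                else:
                    res = correlation_t_test(vectors[name], ref_vec, alpha=alpha,
                                             method_a=name, method_b=reference)
                    # significant *positive* correlation: shape maintained
                    keep = res.decision == REJECT and res.extra["r"] > 0
            except ValueError as exc:
                raise ValueError(f"{gate} gate failed for pair ({name}, {reference}): {exc}") from exc
            gate_results[name].append(res)
            (survivors if keep else removed[gate]).append(name)
        candidates = survivors

    retained = [reference] + candidates
    # preserve the input ordering of the retained list
    retained = [n for n in names if n in set(retained)]
    return SelectionReport(
        reference=reference,
        removed_by_mean_test=removed["mean"],
        removed_by_variance_test=removed["variance"],
        removed_by_correlation_test=removed["correlation"],
        retained=retained,
        all_pairwise=all_pairwise,
        gate_results=gate_results,
    )
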