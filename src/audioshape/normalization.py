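"""The twenty audiogram normalization transforms and dataset augmentation.

Each transform rescales a level vector using summary statistics of a *scope*:
by default the 8 levels of the audiogram being normalized (``per_audiogram``),
optionally the whole dataset (``global``).  Every normalized audiogram keeps
the id and class label of its source, so normalization acts as shape-preserving
data augmentation: a monotone transform leaves the audiogram's shape — the
relative ordering of its levels across frequency — intact.

Registered methods (canonical snake_case names, lookup case-insensitive):

====================  =====================================================
z_score               (x − μ) / σ
linear_scaling        (x − min) / (max − min)
binary                0.8·(x − min)/(max − min) + 0.1
bipolar               1.8·(x − min)/(max − min) − 0.9
min_max               (x − min)(max_n − min_n)/(max − min) + min_n
t_score               (x − μ) / (σ/√n)
differential_moment   (1/N²)(Σxᵢ)² − xᵢ²
variation             (σ/μ)·xᵢ
decimal_inverse_log   10⁻¹²·10^{0.1x}·10⁷
ape_1                 (x̄ − xᵢ) / ((x̄ + xᵢ)/2)
ape_2                 (x̄ − xᵢ) / x̄
arctan_ape_1          arctan of ape_1
arctan_ape_2          arctan of ape_2
gaussian              normal density of xᵢ under N(μ, σ²)
rssv                  x / Σx²
rlssv                 log₁₀(x) / log₁₀(Σx²)
relative_mean         x / x̄
relative_std          x / σ
relative_iqr          x / IQR
robust                (x − median) / IQR
====================  =====================================================

σ, std and variance use the sample form (ddof = 1).  The Gaussian method is a
density value and hence non-monotone; it is registered as printed and the
statistical selection stage is what removes it in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from audioshape.core import Audiogram, DegenerateInputError

__all__ = [
    "ScopeStats",
    "NormalizationMethod",
    "NormalizedDataset",
    "METHOD_NAMES",
    "MONOTONE_AFFINE_METHODS",
    "get_method",
    "list_methods",
    "compute_scope_stats",
    "apply_method",
    "augment",
]


@dataclass(frozen=True)
class ScopeStats:
    """Summary statistics of a normalization scope (one audiogram or a dataset)."""

    mean: float
    std: float  # sample std, ddof=1
    min: float
    max: float
    median: float
    iqr: float
    n: int
    sum_sq: float  # Σ x²

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ScopeStats":
        v = np.asarray(values, dtype=float).ravel()
        return cls(
            mean=float(v.mean()),
            std=float(v.std(ddof=1)),
            min=float(v.min()),
            max=float(v.max()),
            median=float(np.median(v)),
            iqr=float(sps.iqr(v)),
            n=int(v.size),
            sum_sq=float(np.sum(v**2)),
        )


def _need(value: float, statistic: str) -> float:
    if value == 0:
        raise DegenerateInputError(statistic)
    return value


def _span(s: ScopeStats) -> float:
    return _need(s.max - s.min, "max - min")


def _z_score(x, s: ScopeStats):
    return (x - s.mean) / _need(s.std, "sigma")


def _linear_scaling(x, s: ScopeStats):
    return (x - s.min) / _span(s)


def _binary(x, s: ScopeStats):
    return 0.8 * (x - s.min) / _span(s) + 0.1


def _bipolar(x, s: ScopeStats):
    return 1.8 * (x - s.min) / _span(s) - 0.9


def _min_max(x, s: ScopeStats, new_range=(-1.0, 1.0)):
    min_n, max_n = new_range
    return (x - s.min) * (max_n - min_n) / _span(s) + min_n


def _t_score(x, s: ScopeStats):
    return (x - s.mean) / (_need(s.std, "sigma") / np.sqrt(s.n))


def _differential_moment(x, s: ScopeStats):
    total = s.mean * s.n
    return (total**2) / s.n**2 - x**2


def _variation(x, s: ScopeStats):
    return (s.std / _need(s.mean, "mu")) * x


def _decimal_inverse_log(x, s: ScopeStats):
    return 1e-12 * 10.0 ** (0.1 * x) * 1e7


def _ape_1(x, s: ScopeStats):
    denom = (s.mean + x) / 2.0
    if np.any(denom == 0):
        raise DegenerateInputError("(x-bar + x)/2")
    return (s.mean - x) / denom


def _ape_2(x, s: ScopeStats):
    return (s.mean - x) / _need(s.mean, "x-bar")


def _arctan_ape_1(x, s: ScopeStats):
    return np.arctan(_ape_1(x, s))


def _arctan_ape_2(x, s: ScopeStats):
    return np.arctan(_ape_2(x, s))


def _gaussian(x, s: ScopeStats):
    sigma = _need(s.std, "sigma")
    return np.exp(-((x - s.mean) ** 2) / (2 * sigma**2)) / np.sqrt(2 * np.pi * sigma**2)


def _rssv(x, s: ScopeStats):
    return x / _need(s.sum_sq, "sum of squares")


def _rlssv(x, s: ScopeStats):
    if np.any(x <= 0):
        raise DegenerateInputError(
            "log(x)", "RLSSV requires strictly positive levels (log of a nonpositive value)"
        )
    denom = np.log10(_need(s.sum_sq, "sum of squares"))
    return np.log10(x) / _need(denom, "log10(sum of squares)")


def _relative_mean(x, s: ScopeStats):
    return x / _need(s.mean, "x-bar")


def _relative_std(x, s: ScopeStats):
    return x / _need(s.std, "sigma")


def _relative_iqr(x, s: ScopeStats):
    return x / _need(s.iqr, "IQR")


def _robust(x, s: ScopeStats):
    return (x - s.median) / _need(s.iqr, "IQR")


@dataclass(frozen=True)
class NormalizationMethod:
    """A named normalization transform.

    ``transform(levels, scope_stats)`` maps a level vector to a normalized
    vector of the same length; ``params`` carries optional parameters (the new
    range for min_max).
    """

    name: str
    transform: Callable
    params: dict = field(default_factory=dict)

    def __call__(self, levels: np.ndarray, scope_stats: ScopeStats) -> np.ndarray:
        if self.params:
            return self.transform(levels, scope_stats, **self.params)
        return self.transform(levels, scope_stats)


_REGISTRY = {}


def _register(name: str, fn: Callable, **params) -> None:
    key = name.lower()
    if key in _REGISTRY:
        raise ValueError(f"method {name!r} registered twice")
    _REGISTRY[key] = NormalizationMethod(name=name, transform=fn, params=params)


_register("z_score", _z_score)
_register("linear_scaling", _linear_scaling)
_register("binary", _binary)
_register("bipolar", _bipolar)
_register("min_max", _min_max, new_range=(-1.0, 1.0))
_register("t_score", _t_score)
_register("differential_moment", _differential_moment)
_register("variation", _variation)
_register("decimal_inverse_log", _decimal_inverse_log)
_register("ape_1", _ape_1)
_register("ape_2", _ape_2)
_register("arctan_ape_1", _arctan_ape_1)
_register("arctan_ape_2", _arctan_ape_2)
_register("gaussian", _gaussian)
_register("rssv", _rssv)
_register("rlssv", _rlssv)
_register("relative_mean", _relative_mean)
_register("relative_std", _relative_std)
_register("relative_iqr", _relative_iqr)
_register("robust", _robust)

METHOD_NAMES = tuple(_REGISTRY)

# Strictly increasing affine transforms: these preserve Pearson correlation
# with the original levels exactly (r = 1 on any non-constant audiogram),
# i.e. the audiogram's shape.  relative_mean is affine with positive slope
# only when the scope mean is positive (always true for hearing-loss levels).
MONOTONE_AFFINE_METHODS = (
    "z_score",
    "linear_scaling",
    "binary",
    "bipolar",
    "min_max",
    "t_score",
    "relative_mean",
    "relative_std",
    "relative_iqr",
    "robust",
)


def get_method(name: str, minmax_new_range: Optional[Sequence[float]] = None) -> NormalizationMethod:
    """Look up a registered method by (case-insensitive) name."""
    key = name.lower()
    if key not in _REGISTRY:
        raise KeyError(f"unknown normalization method {name!r}; known: {sorted(_REGISTRY)}")
    method = _REGISTRY[key]
    if key == "min_max" and minmax_new_range is not None:
        lo, hi = (float(v) for v in minmax_new_range)
        method = NormalizationMethod(name=method.name, transform=method.transform,
                                     params={"new_range": (lo, hi)})
    return method


def list_methods(names: Optional[Iterable[str]] = None,
                 minmax_new_range: Optional[Sequence[float]] = None) -> list:
    """Resolve ``names`` (or all 20 methods when None) to method objects."""
    if names is None:
        names = METHOD_NAMES
    return [get_method(n, minmax_new_range=minmax_new_range) for n in names]


def compute_scope_stats(audiograms: Sequence[Audiogram]) -> ScopeStats:
    """Global-scope statistics over every level of every audiogram."""
    values = np.concatenate([a.levels for a in audiograms])
    return ScopeStats.from_values(values)


def apply_method(
    method: NormalizationMethod,
    a: Audiogram,
    scope_stats: Optional[ScopeStats] = None,
) -> Audiogram:
    """Normalize one audiogram with one method.

    ``scope_stats`` defaults to the statistics of the audiogram's own 8
    levels (per-audiogram scope); pass dataset-level statistics for global
    scope.  The id and label are preserved; which method produced the vector
    is carried by the enclosing :class:`NormalizedDataset`.
    """
    stats_ = scope_stats if scope_stats is not None else ScopeStats.from_values(a.levels)
    normalized = method(a.levels.astype(float), stats_)
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape != a.levels.shape:
        raise ValueError(f"method {method.name} changed the vector length")
    return a.replace(levels=normalized)


@dataclass
class NormalizedDataset:
    """All audiograms of a source dataset transformed by one method."""

    method_name: str
    audiograms: list
    scope: str = "per_audiogram"
    skipped_ids: list = field(default_factory=list)


def augment(
    dataset: Sequence[Audiogram],
    methods: Sequence[NormalizationMethod],
    scope: str = "per_audiogram",
    on_error: str = "raise",
) -> list:
    """Produce one :class:`NormalizedDataset` per method.

    With ``on_error="raise"`` (default) a degenerate audiogram/method pair
    aborts with the method and audiogram id in the message; with
    ``on_error="skip"`` the pair is dropped and recorded in
    ``skipped_ids`` of the affected dataset.
    """
    if not len(dataset):
        raise ValueError("augment requires a nonempty dataset")
    if not len(methods):
        raise ValueError("augment requires a nonempty method list")
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    global_stats = compute_scope_stats(dataset) if scope == "global" else None
    out = []
    for method in methods:
        normalized, skipped = [], []
        for a in dataset:
            try:
                normalized.append(apply_method(method, a, scope_stats=global_stats))
            except DegenerateInputError as exc:
                if on_error == "raise":
                    raise DegenerateInputError(
                        exc.statistic,
                        f"method {method.name!r}, audiogram {a.id!r}: {exc}",
                    ) from exc
                skipped.append(a.id)
        out.append(NormalizedDataset(method_name=method.name, audiograms=normalized,
                                     scope=scope, skipped_ids=skipped))
    return out
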