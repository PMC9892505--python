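"""Hand-crafted audiogram shape features, staged reduction and nested features.

The base descriptor has 39 features per audiogram (levels H1..H8):

- three averages: A1 = mean(H1..H8), A2 = mean(H2..H5), A3 = mean(H6..H8);
- three steepness slopes, each a level drop over its frequency span in kHz:
  SS1 = (H4 − H8)/4.5, SS2 = (H3 − H6)/2, SS3 = (H2 − H5)/1.5 on the default
  grid (denominators come from the configured grid's frequency differences);
- five summary statistics: min, max, range (max − min), sample std, median;
- ten Pearson correlations against the standard reference audiograms
  N1..N7, S1..S3;
- six coefficients of the degree-5 least-squares polynomial fitted to the
  levels (p5 .. p0) plus the residual = sum of squared differences between
  the audiogram and the fitted polynomial;
- a steepness flag: 1 iff range strictly exceeds 60 dB;
- ten variances vs the references: Σ(Hᵢ − Hᵢ,ref)²/7.

Supervised-stage reduction drops, in order, the 10 reference variances
(39→29), then SS1 and the polynomial coefficients p3..p0 (29→24), then the
correlations r_N2, r_N4, r_N7, r_S1 (24→20).  Ten nested binary features —
interval-membership indicators learned per class — and a quadratic mapping
of the residual onto the class scale bring the final arrangement to
20 + 10 + 1 = 31 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from audioshape.core import Audiogram, ReferenceSet

__all__ = [
    "BASE_FEATURE_NAMES",
    "REDUCTION_STAGES",
    "NESTED_FEATURE_SPEC",
    "FeatureVector",
    "NestedFeatureModel",
    "ResidualMap",
    "base_features",
    "reduce_features",
    "fit_nested",
    "nested_features",
    "fit_residual_map",
    "final_arrangement",
]

_CORR_NAMES = tuple(f"r_{k}" for k in ReferenceSet.KEYS)
_VAR_NAMES = tuple(f"var_{k}" for k in ReferenceSet.KEYS)
_POLY_NAMES = ("p5", "p4", "p3", "p2", "p1", "p0")

BASE_FEATURE_NAMES: Tuple[str, ...] = (
    ("A1", "A2", "A3", "SS1", "SS2", "SS3", "min", "max", "range", "std", "median")
    + _CORR_NAMES
    + _POLY_NAMES
    + ("residual", "steep_flag")
    + _VAR_NAMES
)
assert len(BASE_FEATURE_NAMES) == 39

# stage -> features removed by it
REDUCTION_STAGES: Dict[str, Tuple[str, ...]] = {
    "drop_variances": _VAR_NAMES,
    "drop_minor": ("SS1", "p3", "p2", "p1", "p0"),
    "drop_refs": ("r_N2", "r_N4", "r_N7", "r_S1"),
}

# class id -> base features whose per-class [min, max] intervals define the
# nested indicator for that class
NESTED_FEATURE_SPEC: Dict[int, Tuple[str, ...]] = {
    1: ("A1", "A3"),
    2: ("median", "std"),
    3: ("median",),
    4: ("A2", "A3"),
    5: ("median", "std"),
    6: ("median", "std"),
    7: ("range", "median"),
    8: ("A1",),
    9: ("A3",),
    10: ("A3",),
}

STEEP_RANGE_DB = 60.0  # flag set iff range strictly exceeds this


@dataclass
class FeatureVector:
    """Ordered feature values keyed by a feature-name registry."""

    names: Tuple[str, ...]
    values: np.ndarray
    id: str = ""
    label: Optional[int] = None

    def __post_init__(self):
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.names):
            raise ValueError(
                f"{len(self.names)} feature names but {self.values.size} values"
            )

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None

    def as_dict(self) -> Dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def _steepness_denominators(grid) -> Tuple[float, float, float]:
    f = grid.array
    return (f[7] - f[3], f[5] - f[2], f[4] - f[1])  # 4.5, 2, 1.5 kHz by default


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    cov = np.sum((x - x.mean()) * (y - y.mean())) / (x.size - 1)
    return float(cov / (sx * sy))


def polynomial_residual(levels: np.ndarray, degree: int = 5) -> Tuple[np.ndarray, float]:
    """Least-squares polynomial fit of the levels vs frequency index 1..8.

    Returns the coefficients (highest power first, length degree+1) and the
    residual — the sum of squared differences between the levels and the
    fitted polynomial.
    """
    x = np.arange(1, levels.size + 1, dtype=float)
    coeffs = np.polyfit(x, levels, deg=degree)
    fitted = np.polyval(coeffs, x)
    residual = float(np.sum((levels - fitted) ** 2))
    return coeffs, residual


def base_features(a: Audiogram, refs: ReferenceSet) -> FeatureVector:
    """Compute the 39 base features of one audiogram.

    Raises ``ValueError`` naming the first correlation feature when the
    audiogram is constant (Pearson r undefined).
    """
    h = a.levels.astype(float)
    d1, d2, d3 = _steepness_denominators(a.grid)

    values: Dict[str, float] = {}
    values["A1"] = float(h.mean())
    values["A2"] = float(h[1:5].mean())
    values["A3"] = float(h[5:8].mean())
    values["SS1"] = float((h[3] - h[7]) / d1)
    values["SS2"] = float((h[2] - h[5]) / d2)
    values["SS3"] = float((h[1] - h[4]) / d3)
    values["min"] = float(h.min())
    values["max"] = float(h.max())
    values["range"] = float(h.max() - h.min())
    values["std"] = float(h.std(ddof=1))
    values["median"] = float(np.median(h))

    if h.std(ddof=1) == 0.0:
        raise ValueError(
            f"feature r_{ReferenceSet.KEYS[0]} undefined: audiogram "
            f"{a.id!r} is constant, Pearson correlation has no value"
        )
    for key in ReferenceSet.KEYS:
        ref_levels = refs[key].levels
        if ref_levels.std(ddof=1) == 0.0:
            raise ValueError(f"feature r_{key} undefined: reference {key} is constant")
        values[f"r_{key}"] = _pearson(h, ref_levels)

    coeffs, residual = polynomial_residual(h, degree=5)
    for name, c in zip(_POLY_NAMES, coeffs):
        values[name] = float(c)
    values["residual"] = residual
    values["steep_flag"] = 1.0 if values["range"] > STEEP_RANGE_DB else 0.0

    for key in ReferenceSet.KEYS:
        diff = h - refs[key].levels
        values[f"var_{key}"] = float(np.sum(diff**2) / (h.size - 1))

    vec = np.array([values[n] for n in BASE_FEATURE_NAMES])
    if not np.all(np.isfinite(vec)):
        bad = BASE_FEATURE_NAMES[int(np.argmax(~np.isfinite(vec)))]
        raise ValueError(f"feature {bad!r} is not finite for audiogram {a.id!r}")
    return FeatureVector(names=BASE_FEATURE_NAMES, values=vec, id=a.id, label=a.label)


def reduce_features(fv: FeatureVector, stage: str) -> FeatureVector:
    """Apply one named reduction stage; applying a stage twice is a no-op."""
    if stage not in REDUCTION_STAGES:
        raise ValueError(f"unknown reduction stage {stage!r}; known: {sorted(REDUCTION_STAGES)}")
    drop = set(REDUCTION_STAGES[stage])
    keep = [i for i, n in enumerate(fv.names) if n not in drop]
    return FeatureVector(
        names=tuple(fv.names[i] for i in keep),
        values=fv.values[keep],
        id=fv.id,
        label=fv.label,
    )


def reduce_all(fv: FeatureVector) -> FeatureVector:
    """All three reduction stages in order: 39 → 29 → 24 → 20 features."""
    for stage in ("drop_variances", "drop_minor", "drop_refs"):
        fv = reduce_features(fv, stage)
    return fv


@dataclass
class NestedFeatureModel:
    """Per-class [min, max] intervals of selected base features.

    For each class the interval of each listed feature is the min/max over
    that class's *training* members; membership of a new sample in all of a
    class's intervals (logical AND) yields that class's nested binary feature.
    """

    intervals: Dict[int, Dict[str, Tuple[float, float]]]

    def __post_init__(self):
        for c, feats in self.intervals.items():
            for name, (lo, hi) in feats.items():
                if lo > hi:
                    raise ValueError(f"class {c}, feature {name}: min {lo} > max {hi}")

    @property
    def classes(self) -> Tuple[int, ...]:
        return tuple(sorted(self.intervals))


def fit_nested(train: Sequence[FeatureVector], k: Optional[int] = 10) -> NestedFeatureModel:
    """Learn the per-class feature intervals from labelled training vectors.

    Every class 1..k must have at least one member; ``k=None`` uses whichever
    classes appear in the training labels.  Classes beyond the 10 named in
    the nested-feature table reuse the class-10 feature list.
    """
    by_class: Dict[int, list] = {}
    for fv in train:
        if fv.label is None:
            raise ValueError(f"unlabelled feature vector {fv.id!r} in nested-feature training")
        by_class.setdefault(fv.label, []).append(fv)
    class_ids = sorted(by_class) if k is None else range(1, k + 1)
    intervals: Dict[int, Dict[str, Tuple[float, float]]] = {}
    for c in class_ids:
        members = by_class.get(c)
        if not members:
            raise ValueError(f"class {c} has no training members")
        feat_names = NESTED_FEATURE_SPEC.get(c, NESTED_FEATURE_SPEC[10])
        intervals[c] = {}
        for name in feat_names:
            vals = [m[name] for m in members]
            intervals[c][name] = (min(vals), max(vals))
    return NestedFeatureModel(intervals=intervals)


def nested_features(fv: FeatureVector, model: NestedFeatureModel) -> FeatureVector:
    """Append the binary interval-membership feature of every class."""
    bits = []
    names = []
    for c in model.classes:
        inside = all(
            model.intervals[c][name][0] <= fv[name] <= model.intervals[c][name][1]
            for name in model.intervals[c]
        )
        bits.append(1.0 if inside else 0.0)
        names.append(f"nested_c{c}")
    return FeatureVector(
        names=fv.names + tuple(names),
        values=np.concatenate([fv.values, bits]),
        id=fv.id,
        label=fv.label,
    )


@dataclass
class ResidualMap:
    """Degree-2 polynomial mapping the polynomial-fit residual to a class score.

    Coefficients (c2, c1, c0) are fitted by least squares on training folds:
    score = c2·residual² + c1·residual + c0.
    """

    coefficients: Tuple[float, float, float]

    def __call__(self, residual: float) -> float:
        c2, c1, c0 = self.coefficients
        return c2 * residual**2 + c1 * residual + c0


def fit_residual_map(train: Sequence[FeatureVector]) -> ResidualMap:
    """Fit the quadratic residual → class-label map on labelled vectors."""
    residuals = np.array([fv["residual"] for fv in train])
    labels = []
    for fv in train:
        if fv.label is None:
            raise ValueError(f"unlabelled feature vector {fv.id!r} in residual-map training")
        labels.append(float(fv.label))
    if len(residuals) < 3 or np.allclose(residuals, residuals[0]):
        # underdetermined quadratic: fall back to the constant mean label
        return ResidualMap(coefficients=(0.0, 0.0, float(np.mean(labels))))
    coeffs = np.polyfit(residuals, np.asarray(labels), deg=2)
    return ResidualMap(coefficients=tuple(float(c) for c in coeffs))


def final_arrangement(
    fv: FeatureVector,
    model: NestedFeatureModel,
    rmap: ResidualMap,
) -> FeatureVector:
    """Assemble the final 31-feature arrangement.

    ``fv`` must already be reduced to the 20-feature set (the raw residual
    included); the 10 nested features and the quadratic-mapped residual are
    appended: 20 + 10 + 1 = 31.
    """
    if model is None or rmap is None:
        raise ValueError("nested-feature model and residual map must be fitted first")
    fv = nested_features(fv, model)
    mapped = rmap(fv["residual"])
    return FeatureVector(
        names=fv.names + ("mapped_residual",),
        values=np.append(fv.values, mapped),
        id=fv.id,
        label=fv.label,
    )
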