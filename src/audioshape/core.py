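"""Domain types, audiogram CSV I/O and configuration shared by all stages.

An audiogram is a vector of hearing-threshold levels in dB HL measured at a
fixed grid of test frequencies (default 0.25, 0.5, 1, 1.5, 2, 3, 4 and 6 kHz).
The canonical internal representation is *positive* dB HL — larger values mean
worse hearing; the negative representation (element-wise negation) exists only
as an extra training representation produced by :func:`negate`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AudiogramFormatError",
    "DegenerateInputError",
    "FrequencyGrid",
    "Audiogram",
    "ReferenceSet",
    "PipelineConfig",
    "negate",
    "read_audiograms",
    "write_audiograms",
]


class AudiogramFormatError(ValueError):
    """Raised when an input table does not parse as audiograms."""


class DegenerateInputError(ValueError):
    """Raised when a scope statistic makes a formula undefined.

    Carries the name of the offending statistic (e.g. ``"max - min"``,
    ``"sigma"``, ``"IQR"``) so callers can log or skip precisely.
    """

    def __init__(self, statistic: str, message: Optional[str] = None):
        self.statistic = statistic
        super().__init__(message or f"degenerate input: {statistic} makes the formula undefined")


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered test frequencies in kHz; all stages share one grid.

    Exactly 8 strictly increasing frequencies within [0.125, 8] kHz.  The
    grid also provides the frequency differences that act as denominators of
    the three steepness slopes (4.5, 2 and 1.5 kHz on the default grid).
    """

    freqs_khz: tuple = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0)

    def __post_init__(self):
        f = np.asarray(self.freqs_khz, dtype=float)
        if f.size != 8:
            raise ValueError(f"frequency grid must have exactly 8 entries, got {f.size}")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if f.min() < 0.125 or f.max() > 8.0:
            raise ValueError("frequencies must lie within [0.125, 8] kHz")
        object.__setattr__(self, "freqs_khz", tuple(float(x) for x in f))

    def __len__(self) -> int:
        return len(self.freqs_khz)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs_khz, dtype=float)

    def column_names(self) -> list:
        """Header names for the level columns: the frequency in kHz."""
        return [format(f, "g") for f in self.freqs_khz]


DEFAULT_GRID = FrequencyGrid()


@dataclass
class Audiogram:
    """Hearing-threshold levels (dB HL) of one ear/test on a frequency grid.

    ``sign`` records which representation the levels are in: ``"positive"``
    (canonical, larger = worse hearing) or ``"negative"`` (negated levels used
    as an augmentation sample).  ``label`` is an optional 1-based class id.
    """

    levels: np.ndarray
    id: str = ""
    label: Optional[int] = None
    sign: str = "positive"
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size != len(self.grid):
            raise AudiogramFormatError(
                f"expected {len(self.grid)} thresholds, got {self.levels.size}"
                + (f" (audiogram {self.id!r})" if self.id else "")
            )
        if self.sign not in ("positive", "negative"):
            raise ValueError(f"sign must be 'positive' or 'negative', got {self.sign!r}")
        if self.label is not None:
            self.label = int(self.label)

    def replace(self, **changes) -> "Audiogram":
        return dataclasses.replace(self, **changes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Audiogram):
            return NotImplemented
        return (
            np.array_equal(self.levels, other.levels)
            and self.id == other.id
            and self.label == other.label
            and self.sign == other.sign
            and self.grid == other.grid
        )


def negate(a: Audiogram) -> Audiogram:
    """Return the opposite-sign representation of an audiogram.

    Levels are negated element-wise and the sign flag flipped; id and label
    are preserved.  ``negate`` is an involution.
    """
    flipped = "negative" if a.sign == "positive" else "positive"
    return a.replace(levels=-a.levels, sign=flipped)


@dataclass
class ReferenceSet:
    """The ten standard audiograms used for correlation/variance features.

    Keys N1..N7 are flat-to-moderately-sloping shapes of increasing severity;
    S1..S3 are steep shapes (threshold range above 60 dB).
    """

    standards: dict  # name -> Audiogram

    N_KEYS = ("N1", "N2", "N3", "N4", "N5", "N6", "N7")
    S_KEYS = ("S1", "S2", "S3")
    KEYS = N_KEYS + S_KEYS

    def __post_init__(self):
        if tuple(self.standards.keys()) != self.KEYS:
            missing = set(self.KEYS) - set(self.standards)
            extra = set(self.standards) - set(self.KEYS)
            raise ValueError(
                "reference set must contain exactly N1..N7, S1..S3 in order"
                + (f"; missing {sorted(missing)}" if missing else "")
                + (f"; unexpected {sorted(extra)}" if extra else "")
            )

    def __getitem__(self, key: str) -> Audiogram:
        return self.standards[key]

    def __iter__(self):
        return iter(self.standards.items())

    def levels_matrix(self) -> np.ndarray:
        """(10, 8) matrix of reference levels in key order."""
        return np.vstack([self.standards[k].levels for k in self.KEYS])

    def is_steep(self, key: str) -> bool:
        return key in self.S_KEYS


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline, all governed by one seed."""

    alpha: float = 0.05
    k_range: tuple = (7, 8, 9, 10, 11)
    k_default: int = 10
    n_folds: int = 5
    knn_k: int = 1
    seed: int = 0
    # dataset-level statistics keep between-audiogram severity differences;
    # per-audiogram statistics collapse them (every z-scored audiogram would
    # have mean 0 / std 1, erasing the class signal)
    normalization_scope: str = "global"
    minmax_new_range: tuple = (-1.0, 1.0)
    reference_method: str = "z_score"
    normal_hearing_cutoff_db: float = 20.0
    silhouette_threshold: float = 0.1
    whole_set_fitting: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.normalization_scope not in ("per_audiogram", "global"):
            raise ValueError("normalization_scope must be 'per_audiogram' or 'global'")
        self.k_range = tuple(int(k) for k in self.k_range)
        self.minmax_new_range = tuple(float(v) for v in self.minmax_new_range)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Load a config from a YAML (or JSON — a YAML subset) file."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["minmax_new_range"] = list(self.minmax_new_range)
        return d


def _parse_grid_from_header(columns: Sequence[str]) -> tuple:
    """Split a CSV header into (id?, level columns, label?) and build the grid."""
    cols = list(columns)
    has_id = bool(cols) and cols[0].strip().lower() == "id"
    if has_id:
        cols = cols[1:]
    has_label = bool(cols) and cols[-1].strip().lower() == "label"
    if has_label:
        cols = cols[:-1]
    try:
        freqs = [float(c) for c in cols]
    except ValueError as exc:
        raise AudiogramFormatError(
            f"header columns must be frequencies in kHz (plus optional 'id'/'label'): {exc}"
        ) from None
    if len(freqs) != 8:
        raise AudiogramFormatError(f"expected 8 frequency columns, found {len(freqs)}")
    return has_id, FrequencyGrid(tuple(freqs)), has_label


def read_audiograms(
    path: Union[str, Path],
    sign: str = "positive",
    grid: Optional[FrequencyGrid] = None,
) -> list:
    """Read audiograms from a CSV file.

    Expected dialect: comma-separated, UTF-8, one header row whose level
    columns are the frequencies in kHz; an optional leading ``id`` column and
    an optional trailing ``label`` column.  Row order is preserved.

    Raises :class:`AudiogramFormatError` naming the row/column on malformed
    input (wrong column count, non-numeric cell, grid mismatch).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    has_id, file_grid, has_label = _parse_grid_from_header(df.columns)
    if grid is not None and file_grid != grid:
        raise AudiogramFormatError(
            f"file frequency grid {file_grid.freqs_khz} does not match configured grid {grid.freqs_khz}"
        )
    use_grid = grid or file_grid

    level_cols = df.columns[1:9] if has_id else df.columns[0:8]
    out = []
    for row_idx, row in df.iterrows():
        if row.isna().any():
            bad = row.index[row.isna()][0]
            raise AudiogramFormatError(f"row {row_idx + 1}: missing value in column {bad!r}")
        try:
            levels = np.array([float(row[c]) for c in level_cols])
        except ValueError:
            bad = next(c for c in level_cols if not _is_number(row[c]))
            raise AudiogramFormatError(
                f"row {row_idx + 1}: non-numeric threshold {row[bad]!r} in column {bad!r}"
            ) from None
        label = None
        if has_label:
            raw = row[df.columns[-1]]
            if not _is_number(raw) or int(float(raw)) != float(raw):
                raise AudiogramFormatError(f"row {row_idx + 1}: label {raw!r} is not an integer")
            label = int(float(raw))
        ident = str(row[df.columns[0]]) if has_id else f"row{row_idx + 1}"
        out.append(Audiogram(levels=levels, id=ident, label=label, sign=sign, grid=use_grid))
    return out


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def write_audiograms(audiograms: Iterable[Audiogram], path: Union[str, Path]) -> None:
    """Write audiograms to the CSV dialect read by :func:`read_audiograms`.

    Finite levels round-trip bit-exactly (written with ``repr`` precision).
    """
    audiograms = list(audiograms)
    path = Path(path)
    if not audiograms:
        grid = DEFAULT_GRID
        header = ["id"] + grid.column_names()
        path.write_text(",".join(header) + "\n", encoding="utf-8")
        return
    grid = audiograms[0].grid
    with_labels = any(a.label is not None for a in audiograms)
    header = ["id"] + grid.column_names() + (["label"] if with_labels else [])
    lines = [",".join(header)]
    for a in audiograms:
        if a.grid != grid:
            raise AudiogramFormatError(f"audiogram {a.id!r} is on a different frequency grid")
        cells = [a.id] + [repr(float(v)) for v in a.levels]
        if with_labels:
            cells.append("" if a.label is None else str(a.label))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
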