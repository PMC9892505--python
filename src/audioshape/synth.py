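"""Synthetic audiogram datasets emulating a quantized standard-audiogram set.

The generator produces data with the structure the pipeline assumes: ten
hearing-loss shape families — seven flat-to-moderately-sloping "N" shapes of
increasing severity and three steep "S" shapes whose threshold range exceeds
60 dB — plus a normal-hearing family that the annotation stage removes.
Samples are archetype levels plus Gaussian noise, quantized to a 5 dB step
as audiometers report thresholds.

The genuine standard-audiogram table is not redistributable, so its values
are not embedded; the archetype levels here are synthetic stand-ins chosen
to cover mild through profound loss.  Hearing-loss archetypes keep a 25 dB
floor — the set emulates data *after* the normal-hearing subset (all
thresholds at or below 20 dB) has been removed, and strictly positive levels
keep every normalization method (including the logarithmic one) defined.
Users holding real quantized data supply it via the standard CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from audioshape.core import Audiogram, FrequencyGrid, ReferenceSet

__all__ = [
    "ArchetypeSpec",
    "REFERENCE_LEVELS",
    "NORMAL_ARCHETYPE_LEVELS",
    "make_reference_set",
    "bisgaard_like_archetypes",
    "make_dataset",
]

# Synthetic stand-ins for the ten standard reference audiograms (dB HL at
# 0.25, 0.5, 1, 1.5, 2, 3, 4, 6 kHz).  N1..N7: non-decreasing, increasing
# severity, range <= 60 dB; S1..S3: steep, range > 60 dB.  All multiples of 5.
REFERENCE_LEVELS = {
    "N1": (25, 25, 25, 30, 30, 35, 40, 45),
    "N2": (30, 35, 35, 40, 45, 50, 55, 55),
    "N3": (40, 45, 45, 50, 55, 60, 65, 70),
    "N4": (50, 55, 60, 65, 70, 70, 75, 80),
    "N5": (60, 65, 70, 75, 80, 85, 85, 90),
    "N6": (70, 75, 80, 85, 90, 95, 100, 105),
    "N7": (85, 90, 95, 100, 105, 110, 115, 115),
    "S1": (25, 30, 45, 70, 85, 90, 95, 95),
    "S2": (35, 40, 60, 80, 95, 105, 110, 110),
    "S3": (45, 50, 70, 95, 110, 115, 120, 120),
}

NORMAL_ARCHETYPE_LEVELS = (0, 0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One shape family: base levels plus sampling parameters."""

    name: str
    levels: tuple
    steep: bool = False
    n_samples: int = 6
    noise_sd: float = 5.0  # dB
    quantum: float = 5.0  # dB step of the audiometer

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.quantum <= 0:
            raise ValueError("quantum must be > 0")
        if len(self.levels) != 8:
            raise ValueError("archetype levels must have 8 entries")


def make_reference_set(seed: int = 0, grid: Optional[FrequencyGrid] = None) -> ReferenceSet:
    """The ten standard reference audiograms (deterministic; seed unused)."""
    grid = grid or FrequencyGrid()
    standards = {
        key: Audiogram(levels=np.array(levels, dtype=float), id=key, grid=grid)
        for key, levels in REFERENCE_LEVELS.items()
    }
    return ReferenceSet(standards=standards)


def bisgaard_like_archetypes(
    n_samples: int = 6,
    noise_sd: float = 5.0,
    quantum: float = 5.0,
    include_normal: bool = True,
) -> List[ArchetypeSpec]:
    """The default preset: ten hearing-loss families plus a normal one.

    With 6 samples per family the preset yields 66 audiograms, 60 of which
    survive normal-hearing removal — the scale of a quantized
    standard-audiogram set.
    """
    specs = [
        ArchetypeSpec(name=key, levels=tuple(levels), steep=key.startswith("S"),
                      n_samples=n_samples, noise_sd=noise_sd, quantum=quantum)
        for key, levels in REFERENCE_LEVELS.items()
    ]
    if include_normal:
        specs.append(
            ArchetypeSpec(name="normal", levels=NORMAL_ARCHETYPE_LEVELS,
                          n_samples=n_samples, noise_sd=noise_sd, quantum=quantum)
        )
    return specs


def make_dataset(
    archetypes: Sequence[ArchetypeSpec],
    seed: int = 0,
    grid: Optional[FrequencyGrid] = None,
) -> List[Audiogram]:
    """Sample a labelled dataset: archetype levels + noise, quantized.

    Labels are the 1-based archetype indices; every level is an integer
    multiple of the archetype's quantum.  Reproducible: the same seed yields
    the identical dataset.
    """
    if not len(archetypes):
        raise ValueError("archetype list must be nonempty")
    grid = grid or FrequencyGrid()
    rng = np.random.default_rng(seed)
    out: List[Audiogram] = []
    for label, spec in enumerate(archetypes, start=1):
        base = np.asarray(spec.levels, dtype=float)
        for j in range(spec.n_samples):
            noisy = base + rng.normal(0.0, spec.noise_sd, size=base.size)
            quantized = np.round(noisy / spec.quantum) * spec.quantum
            out.append(
                Audiogram(
                    levels=quantized,
                    id=f"{spec.name}_{j + 1}",
                    label=label,
                    grid=grid,
                )
            )
    return out
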