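"""Vehicle-normalized viability grids and Bliss-independence synergy scoring.

Signals are normalized to the mean vehicle (both doses zero) signal to give
surviving fractions; the effect of a dose pair is 1 minus the surviving
fraction, clamped to [0, 1].  The Bliss expectation for a combination is
E_A + E_B - E_A*E_B from the monotherapy effects; positive excess over it
indicates supra-additivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ViabilityGrid:
    """Replicate-resolved dose-pair viability, normalized to vehicle.

    ``viability[i, j, k]`` is the surviving fraction at ``doses_a[i]`` x
    ``doses_b[j]`` in replicate ``k`` (NaN where a replicate is missing).
    Both dose vectors include 0 and viability at (0, 0) is 1 by construction.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape[:2] != (self.doses_a.size, self.doses_b.size):
            raise ValidationError("viability shape does not match dose vectors")
        if 0.0 not in self.doses_a or 0.0 not in self.doses_b:
            raise ValidationError("both dose vectors must include 0 (vehicle)")

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "ViabilityGrid":
        """Build a grid from long-format raw signals
        (dose_a, dose_b, replicate, signal), normalizing to vehicle."""
        required = {"dose_a", "dose_b", "replicate", "signal"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"long table missing column(s) {sorted(missing)}")
        vehicle = frame[(frame["dose_a"] == 0) & (frame["dose_b"] == 0)]
        fractions = surviving_fraction(
            frame["signal"].to_numpy(dtype=float),
            vehicle["signal"].tolist(),
        )
        frame = frame.assign(fraction=fractions)
        doses_a = np.sort(frame["dose_a"].unique())
        doses_b = np.sort(frame["dose_b"].unique())
        replicates = np.sort(frame["replicate"].unique())
        grid = np.full((doses_a.size, doses_b.size, replicates.size), np.nan)
        ai = {d: i for i, d in enumerate(doses_a)}
        bj = {d: j for j, d in enumerate(doses_b)}
        rk = {r: k for k, r in enumerate(replicates)}
        for row in frame.itertuples(index=False):
            grid[ai[row.dose_a], bj[row.dose_b], rk[row.replicate]] = row.fraction
        return cls(doses_a=doses_a, doses_b=doses_b, viability=grid)

    def mean_viability(self) -> np.ndarray:
        """Replicate-mean surviving fraction per dose pair (NaN where a dose
        pair was never measured)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.viability, axis=2)

    def sd_viability(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.viability, axis=2, ddof=1)

    def effect(self) -> np.ndarray:
        """Replicate-mean effect (1 - viability) clamped to [0, 1]."""
        return np.clip(1.0 - self.mean_viability(), 0.0, 1.0)


@dataclass(frozen=True)
class BlissResult:
    """Expected and excess effect matrices for one grid."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    observed_effect: np.ndarray
    expected_effect: np.ndarray
    excess: np.ndarray
    mean_excess: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, da in enumerate(self.doses_a):
            for j, db in enumerate(self.doses_b):
                rows.append(
                    (da, db, self.observed_effect[i, j],
                     self.expected_effect[i, j], self.excess[i, j])
                )
        return pd.DataFrame(
            rows,
            columns=["dose_a", "dose_b", "observed_effect",
                     "expected_effect", "bliss_excess"],
        )


def surviving_fraction(signal, vehicle_signals: Sequence[float]):
    """Signal relative to the mean vehicle signal.  Values above 1 are
    permitted here; clamping happens only when effects are computed."""
    if len(vehicle_signals) == 0:
        raise ValidationError("vehicle signal list is empty")
    mean_vehicle = float(np.mean(vehicle_signals))
    if mean_vehicle <= 0:
        raise ValidationError(f"vehicle mean must be > 0, got {mean_vehicle}")
    return signal / mean_vehicle


def bliss_excess(effect_a: float, effect_b: float, effect_ab: float) -> float:
    """Observed combination effect minus the independence expectation
    E_A + E_B - E_A*E_B; positive means supra-additive."""
    for name, value in (("effect_a", effect_a), ("effect_b", effect_b),
                        ("effect_ab", effect_ab)):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {value}")
    expected = effect_a + effect_b - effect_a * effect_b
    return effect_ab - expected


def bliss_grid(grid: ViabilityGrid) -> BlissResult:
    """Per-cell Bliss expectation from the monotherapy rows/columns and the
    excess of the observed combination effect over it.

    ``mean_excess`` averages over cells where both doses are nonzero; excess
    is 0 by definition wherever either dose is 0.
    """
    effect = grid.effect()
    i0 = int(np.where(grid.doses_a == 0)[0][0])
    j0 = int(np.where(grid.doses_b == 0)[0][0])
    mono_a = effect[:, j0]  # effect of drug A alone, per dose_a
    mono_b = effect[i0, :]  # effect of drug B alone, per dose_b
    if np.isnan(mono_a).any():
        dose = grid.doses_a[int(np.where(np.isnan(mono_a))[0][0])]
        raise ValidationError(f"missing monotherapy measurement for dose_a={dose}")
    if np.isnan(mono_b).any():
        dose = grid.doses_b[int(np.where(np.isnan(mono_b))[0][0])]
        raise ValidationError(f"missing monotherapy measurement for dose_b={dose}")

    expected = mono_a[:, None] + mono_b[None, :] - mono_a[:, None] * mono_b[None, :]
    excess = effect - expected
    excess[i0, :] = 0.0
    excess[:, j0] = 0.0
    combo = np.ones_like(excess, dtype=bool)
    combo[i0, :] = False
    combo[:, j0] = False
    mean_excess = float(np.nanmean(excess[combo])) if combo.any() else 0.0
    return BlissResult(
        doses_a=grid.doses_a,
        doses_b=grid.doses_b,
        observed_effect=effect,
        expected_effect=expected,
        excess=excess,
        mean_excess=mean_excess,
    )
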