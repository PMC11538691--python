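"""Sedimentation-assay quantification: calibration and the 1 - [s]/[t] level.

A condensation (or, with lipopolysaccharide micelles, agglutination) assay
centrifuges a protein sample and measures the total concentration [t] and
the supernatant concentration [s]; the pellet is [p] = [t] - [s] since it
cannot be resuspended reliably.  The assay statistic is the level

    level = 1 - [s]/[t]

the fraction of protein that left solution.  Concentrations come either
from A280 directly or from a Bradford readout calibrated as an ordinary
least-squares line of A594/A466 ratio against BSA standard concentration.

Replicates are averaged at the level stage and their sd is propagated to
the report; nothing is silently clamped — a noisy level outside [0, 1] is
reported raw with a warning flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CalibrationLine:
    """OLS line ratio = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    standards: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class AssayMeasurement:
    """One total/supernatant pair and its sedimentation level.

    ``pellet = total - supernatant`` by construction, so conservation
    total = supernatant + pellet holds exactly.
    """

    label: str
    total: float
    supernatant: float
    pellet: float = field(init=False)
    level: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pellet", self.total - self.supernatant)
        object.__setattr__(self, "level", level(self.total, self.supernatant))


class DegenerateDesignError(ValueError):
    """All calibration standards share one concentration."""


class OutOfRangeWarning(UserWarning):
    """A derived quantity fell outside its physical range."""


def calibrate(standards: Sequence[tuple[float, float]]) -> CalibrationLine:
    """Ordinary least-squares calibration line from (conc, ratio) standards.

    Requires at least two distinct concentrations.  A non-positive slope
    is physically suspect (more protein should raise the ratio) and
    triggers a warning but not an error.
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    ratio = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise DegenerateDesignError("all standard concentrations identical")
    fit = stats.linregress(conc, ratio)
    if fit.slope <= 0:
        warnings.warn("calibration slope is not positive", OutOfRangeWarning,
                      stacklevel=2)
    return CalibrationLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        standards=tuple((float(c), float(r)) for c, r in standards),
    )


def ratio_to_conc(line: CalibrationLine, ratio: float) -> float:
    """Invert the calibration line; warns when the result is negative."""
    if line.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot invert")
    conc = (ratio - line.intercept) / line.slope
    if conc < 0:
        warnings.warn(
            f"ratio {ratio} below calibration range (conc {conc:.4g} < 0)",
            OutOfRangeWarning, stacklevel=2)
    return conc


def level(total: float, supernatant: float) -> float:
    """Sedimentation level 1 - [s]/[t].

    0 means fully soluble, 1 fully sedimented.  Values outside [0, 1]
    (supernatant exceeding total through measurement noise) are returned
    raw with an :class:`OutOfRangeWarning`, never clamped.
    """
    if total <= 0:
        raise ValueError("total concentration must be positive")
    if supernatant < 0:
        raise ValueError("supernatant concentration must be non-negative")
    value = 1.0 - supernatant / total
    if value < 0.0:
        warnings.warn(
            f"level {value:.4g} below 0 (supernatant {supernatant} exceeds "
            f"total {total})", OutOfRangeWarning, stacklevel=2)
    return value


def aggregate_replicates(label: str,
                         totals: Sequence[float],
                         supernatants: Sequence[float],
                         ) -> tuple[float, float, int]:
    """Mean and sd of per-replicate levels for one condition.

    Returns (mean level, sd of levels, n).  Levels are computed per
    replicate first, then averaged (sd is the ddof=1 sample sd; 0 for a
    single replicate).
    """
    if len(totals) != len(supernatants) or not totals:
        raise ValueError("replicate lists must be non-empty and equal length")
    levels = [level(t, s) for t, s in zip(totals, supernatants)]
    mean = float(np.mean(levels))
    sd = float(np.std(levels, ddof=1)) if len(levels) > 1 else 0.0
    return mean, sd, len(levels)


def compare_levels(measurements: Sequence[AssayMeasurement],
                   reference_label: str,
                   ) -> list[tuple[str, float]]:
    """Relative change of each condition's level versus a reference.

    ``relative_change = (level_ref - level_x) / level_ref``, so 0.20
    means the condition sediments 20% less than the reference.
    """
    ref = [m for m in measurements if m.label == reference_label]
    if not ref:
        raise ValueError(f"reference label {reference_label!r} not present")
    ref_level = ref[0].level
    if ref_level <= 0:
        raise ValueError("reference level must be positive")
    return [(m.label, (ref_level - m.level) / ref_level)
            for m in measurements if m.label != reference_label]
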