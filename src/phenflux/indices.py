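"""Insulin-sensitivity indices, AUC utilities and baseline conventions.

HOMA-IR and the composite (Matsuda) whole-body insulin-sensitivity index are
computed from glucose in mmol/L and insulin in pmol/L, converted internally
to the conventional mg/dL and μU/mL with the factors 18 and 7.18.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .domain import (
    Constants,
    ConfigError,
    DomainError,
    MissingDataError,
)

__all__ = [
    "GlucoseInsulinProfile",
    "homa_ir",
    "matsuda",
    "auc",
    "baseline_summary",
]


@dataclass
class GlucoseInsulinProfile:
    """Fasting values plus postprandial series over 0–120 min."""

    fasting_glucose: float  # mmol/L
    fasting_insulin: float  # pmol/L
    times: np.ndarray  # min, within [0, 120]
    glucose: np.ndarray  # mmol/L
    insulin: np.ndarray  # pmol/L

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        if self.fasting_glucose <= 0 or self.fasting_insulin <= 0:
            raise DomainError("fasting glucose and insulin must be > 0")
        if np.any(self.glucose <= 0) or np.any(self.insulin <= 0):
            raise DomainError("postprandial glucose and insulin must be > 0")


def homa_ir(
    fasting_glucose: float,
    fasting_insulin: float,
    constants: Constants = Constants(),
) -> float:
    """HOMA-IR = glucose [mmol/L] × insulin [pmol/L] / (22.5 × 7.18)."""
    if fasting_glucose <= 0 or fasting_insulin <= 0:
        raise DomainError("fasting glucose and insulin must be > 0")
    return (
        fasting_glucose
        * fasting_insulin
        / (constants.homa_denominator * constants.insulin_conversion)
    )


def _window_mean(times, values, how: str) -> float:
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if how == "arithmetic" or t.size == 1:
        return float(np.mean(y))
    if how != "trapezoid":
        raise ConfigError(f"unknown mean kind {how!r}")
    order = np.argsort(t)
    t, y = t[order], y[order]
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def matsuda(
    profile: GlucoseInsulinProfile,
    constants: Constants = Constants(),
    mean: str = "trapezoid",
) -> float:
    """Composite whole-body insulin sensitivity index.

    10000 / sqrt(Ḡ·18 × Ī/7.18 × G₀·18 × I₀/7.18) with the 0–120 min means
    taken as time-weighted trapezoid means by default (sampling is
    non-uniform); ``mean="arithmetic"`` for the simple mean.
    """
    g_mean = _window_mean(profile.times, profile.glucose, mean)
    i_mean = _window_mean(profile.times, profile.insulin, mean)
    product = (
        (g_mean * constants.glucose_conversion)
        * (i_mean / constants.insulin_conversion)
        * (profile.fasting_glucose * constants.glucose_conversion)
        * (profile.fasting_insulin / constants.insulin_conversion)
    )
    if product <= 0:
        raise DomainError("glucose/insulin product must be positive")
    return 10000.0 / math.sqrt(product)


def auc(
    times,
    values,
    t_range: tuple[float, float] | None = None,
    imputation: str = "linear",
    kind: str = "total",
    baseline: float | None = None,
) -> float:
    """Trapezoid area under the curve, value×min.

    Interior missing values (NaN) are linearly interpolated when
    ``imputation="linear"``; leading/trailing missing values inside the range
    are a boundary error (no extrapolation).  ``kind="incremental"``
    subtracts ``baseline`` (default: the first in-range value) before
    integrating.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float).copy()
    if t_range is not None:
        keep = (t >= t_range[0]) & (t <= t_range[1])
        t, y = t[keep], y[keep]
    order = np.argsort(t)
    t, y = t[order], y[order]
    finite = np.isfinite(y)
    if finite.sum() < 2:
        raise MissingDataError("need >= 2 non-missing points for AUC")
    if not finite.all():
        if imputation == "none":
            t, y = t[finite], y[finite]
        elif imputation == "linear":
            if not (finite[0] and finite[-1]):
                raise MissingDataError(
                    "leading/trailing missing values cannot be imputed "
                    "(no extrapolation)"
                )
            y[~finite] = np.interp(t[~finite], t[finite], y[finite])
        else:
            raise ConfigError(f"unknown imputation {imputation!r}")
    if kind == "incremental":
        base = y[0] if baseline is None else baseline
        y = y - base
    elif kind != "total":
        raise ConfigError(f"unknown AUC kind {kind!r}")
    return float(np.trapezoid(y, t))


def baseline_summary(times, values, quantity_kind: str) -> float:
    """Pre-meal baseline per the study conventions.

    concentration → mean of the −60 and −30 min values; kinetics → the −45
    midpoint value; hormone → the −30 min value.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)

    def pick(time: float) -> float:
        idx = np.flatnonzero(t == time)
        if idx.size == 0 or not np.isfinite(y[idx[0]]):
            raise MissingDataError(f"required pre-meal value at t={time} missing")
        return float(y[idx[0]])

    if quantity_kind == "concentration":
        return 0.5 * (pick(-60.0) + pick(-30.0))
    if quantity_kind == "kinetics":
        return pick(-45.0)
    if quantity_kind == "hormone":
        return pick(-30.0)
    raise ConfigError(f"unknown quantity kind {quantity_kind!r}")
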