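"""Shared types, constants, units and the study time grid.

Everything downstream of the tracer arithmetic speaks the vocabulary defined
here: subjects, tracer protocols, the labeled meal, site-tagged plasma
time-series with per-isotopologue tracer-to-tracee ratios (TTR), femoral blood
flow, and biopsy enrichments.

Unit conventions (used consistently across the package):

* time — minutes relative to meal ingestion (meal at 0; tracers start at −150)
* concentrations — μmol/L plasma
* enrichments — TTR, dimensionless
* whole-body fluxes — μmol per kg lean mass (LM) per minute
* protein turnover — g protein per day per kg LM
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("phenflux")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class PhenfluxError(Exception):
    """Base class for all package errors."""


class DomainError(PhenfluxError, ValueError):
    """An input violates a physical/domain precondition (e.g. mass <= 0)."""


class ConfigError(PhenfluxError, ValueError):
    """A configuration value is invalid (e.g. meal labeling ratio r <= 0)."""


class GridError(PhenfluxError, ValueError):
    """The time grid is unusable (non-increasing times, too few points)."""


class MissingDataError(PhenfluxError, ValueError):
    """A required sample, channel or column is absent."""


class DegenerateEnrichmentError(PhenfluxError, ValueError):
    """An enrichment needed in a denominator is zero or negative."""


class AlignmentError(PhenfluxError, ValueError):
    """Two series that must share a time grid do not."""


# ---------------------------------------------------------------------------
# Constants and the study grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Constants:
    """Physiological and unit-conversion constants.

    pool_fraction_pv
        Effective volume of distribution of the rapidly mixing amino-acid
        pool, L per kg *body weight* (0.125 for both phenylalanine and
        tyrosine).  :func:`effective_pool_volume` rescales it to per-kg-LM.
    phe_per_gram_protein
        Average phenylalanine content of mixed body protein, μmol/g;
        converts phenylalanine fluxes to protein turnover.
    homa_denominator, insulin_conversion, glucose_conversion
        22.5 (HOMA normalisation), 7.18 pmol/L per μU/mL (insulin) and
        18 mg/dL per mmol/L (glucose).
    """

    pool_fraction_pv: float = 0.125
    phe_per_gram_protein: float = 273.0
    homa_denominator: float = 22.5
    insulin_conversion: float = 7.18
    glucose_conversion: float = 18.0
    minutes_per_day: float = 1440.0

    def __post_init__(self) -> None:
        for name in (
            "pool_fraction_pv",
            "phe_per_gram_protein",
            "homa_denominator",
            "insulin_conversion",
            "glucose_conversion",
            "minutes_per_day",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"Constants.{name} must be strictly positive")


#: Full sampling grid of a study visit (min relative to meal).  The −150
#: sample precedes the tracer prime and provides the background enrichment.
STUDY_GRID: tuple[int, ...] = (
    -150, -60, -30, 10, 20, 30, 40, 50, 60, 90, 120, 180, 240, 300, 360,
)

#: Times at which substrate-kinetics samples exist (everything after −150).
KINETIC_TIMES: tuple[int, ...] = STUDY_GRID[1:]

#: Time of the background (pre-prime) sample.
BACKGROUND_TIME: int = -150

GROUPS = ("healthy_weight", "obesity")
VISITS = ("saline", "il6r_ab")
SITES = ("artery", "femoral_vein", "epigastric_vein", "antecubital")

PHE = "phenylalanine"
TYR = "tyrosine"

#: Enrichment channels: name -> (analyte, isotopologues summed).
#: D8-phe transaminates to D7-phe (and onward to D7/D6-tyr), so the sums of
#: D8+D7 phenylalanine and D7+D6 tyrosine carry the infused label; D5-phe
#: carries the meal label; the D5+D7+D8 sum is the FSR precursor channel.
CHANNELS: dict[str, tuple[str, tuple[str, ...]]] = {
    "phe_d8d7": (PHE, ("d8", "d7")),
    "tyr_d7d6": (TYR, ("d7", "d6")),
    "phe_d5": (PHE, ("d5",)),
    "tyr_d2": (TYR, ("d2",)),
    "phe_all": (PHE, ("d5", "d7", "d8")),
}


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str
    body_weight: float  # kg
    lean_mass: float  # kg
    visit: str = "saline"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DomainError(f"unknown group {self.group!r}")
        if self.visit not in VISITS:
            raise DomainError(f"unknown visit {self.visit!r}")
        if not 0 < self.lean_mass < self.body_weight:
            raise DomainError(
                "require 0 < lean_mass < body_weight, got "
                f"LM={self.lean_mass}, BW={self.body_weight}"
            )


@dataclass(frozen=True)
class TracerProtocol:
    """Primed-continuous infusion protocol for one tracer."""

    tracer_id: str  # {"phe_d8", "tyr_d2"}
    prime: float  # μmol per kg LM
    continuous_rate_nominal: float  # μmol per kg LM per min
    infusate_concentration: float  # μmol per mL
    pump_flow: float  # mL per min

    def __post_init__(self) -> None:
        if self.tracer_id not in ("phe_d8", "tyr_d2"):
            raise DomainError(f"unknown tracer_id {self.tracer_id!r}")
        for name in ("prime", "continuous_rate_nominal",
                     "infusate_concentration", "pump_flow"):
            if getattr(self, name) < 0:
                raise DomainError(f"TracerProtocol.{name} must be >= 0")


@dataclass(frozen=True)
class MealSpec:
    """The labeled liquid mixed meal.

    ``d5_to_tracee_ratio_r`` is the tracer:tracee ratio of D5-phenylalanine
    to unlabeled phenylalanine in the meal protein (intrinsically labeled
    casein); it converts the plasma D5 appearance back to meal-derived
    phenylalanine appearance.
    """

    casein_grams: float
    d5_to_tracee_ratio_r: float
    total_phe_ingested: float  # μmol
    energy_kcal: float = 631.0
    volume_ml: float = 400.0
    ingestion_time: float = 0.0  # min

    def __post_init__(self) -> None:
        if not 0 < self.d5_to_tracee_ratio_r < 1:
            raise ConfigError("meal labeling ratio r must lie in (0, 1)")
        if not self.total_phe_ingested > 0:
            raise ConfigError("total_phe_ingested must be positive")


@dataclass(frozen=True)
class PlasmaSample:
    """One analyte at one time and sampling site.

    ``ttr`` maps isotopologue labels (``d8``, ``d7``, ``d5`` for
    phenylalanine; ``d2``, ``d7``, ``d6`` for tyrosine) to tracer-to-tracee
    ratios.  Missing values are represented as ``math.nan`` (or an absent
    key), never as silent zeros.
    """

    time: float
    site: str
    analyte: str
    concentration: float
    ttr: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise DomainError(f"unknown site {self.site!r}")
        if not math.isnan(self.concentration) and self.concentration < 0:
            raise DomainError("concentration must be >= 0 or missing (NaN)")
        for iso, value in self.ttr.items():
            if not math.isnan(value) and value < 0:
                raise DomainError(f"TTR[{iso}] must be >= 0 or missing (NaN)")


@dataclass
class PlasmaSeries:
    """Ordered per-site collection of :class:`PlasmaSample`.

    Samples may cover several analytes; within each analyte the supplied
    order must have strictly increasing times (shuffled inputs are rejected,
    not silently repaired).
    """

    subject_id: str
    visit: str
    site: str
    samples: list[PlasmaSample]

    def __post_init__(self) -> None:
        for analyte in self.analytes():
            times = [s.time for s in self.samples if s.analyte == analyte]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise GridError(
                    f"times not strictly increasing for analyte {analyte!r} "
                    f"at site {self.site!r}"
                )

    def analytes(self) -> list[str]:
        return sorted({s.analyte for s in self.samples})

    def times(self, analyte: str) -> np.ndarray:
        return np.array(
            [s.time for s in self.samples if s.analyte == analyte], dtype=float
        )

    def sample_at(self, time: float, analyte: str) -> PlasmaSample:
        for s in self.samples:
            if s.analyte == analyte and s.time == time:
                return s
        raise MissingDataError(
            f"no {analyte!r} sample at t={time} for site {self.site!r}"
        )

    def concentration_series(self, analyte: str) -> tuple[np.ndarray, np.ndarray]:
        rows = [s for s in self.samples if s.analyte == analyte]
        if not rows:
            raise MissingDataError(f"no samples for analyte {analyte!r}")
        t = np.array([s.time for s in rows], dtype=float)
        c = np.array([s.concentration for s in rows], dtype=float)
        return t, c

    def channel_series(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Times and pooled TTR for an enrichment channel (NaN = missing)."""
        analyte, _ = _channel_spec(channel)
        rows = [s for s in self.samples if s.analyte == analyte]
        if not rows:
            raise MissingDataError(f"no samples for analyte {analyte!r}")
        t = np.array([s.time for s in rows], dtype=float)
        e = np.array([_pooled_ttr_or_nan(s, channel) for s in rows], dtype=float)
        return t, e


@dataclass
class BloodFlowSeries:
    """Femoral arterial blood flow, L/min."""

    time: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.time.shape != self.flow.shape:
            raise GridError("flow and time arrays must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise GridError("flow times must be strictly increasing")
        if np.any(self.flow[np.isfinite(self.flow)] <= 0):
            raise DomainError("blood flow must be strictly positive")

    def at(self, times: np.ndarray) -> np.ndarray:
        """Linearly interpolate flow at the requested times (no extrapolation
        beyond the measured range; the ends are held constant)."""
        return np.interp(np.asarray(times, dtype=float), self.time, self.flow)


@dataclass(frozen=True)
class BiopsyEnrichment:
    """Protein-bound and free-pool phenylalanine enrichment of one biopsy."""

    time: float
    protein_bound_ttr: float  # pooled D5+D7+D8 in protein
    free_pool_ttr: float

    def __post_init__(self) -> None:
        for name in ("protein_bound_ttr", "free_pool_ttr"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0 <= v < 1:
                raise DomainError(f"BiopsyEnrichment.{name} must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class KineticsResult:
    """Whole-body phenylalanine kinetics on the midpoint grid.

    Fluxes are μmol/kg LM/min; ``*_g_day`` entries are g protein/day/kg LM.
    ``n_clipped`` counts negative flux estimates clipped to zero.
    """

    midpoint_times: np.ndarray
    ra_total: np.ndarray
    rd_total: np.ndarray
    ra_oral: np.ndarray
    ra_endo: np.ndarray
    hydroxylation: np.ndarray
    synthesis_rate: np.ndarray
    synthesis_g_day: np.ndarray
    degradation_g_day: np.ndarray
    net_gain_g_day: np.ndarray
    endo_mode: str = "simple"
    tracer_rate: float = 0.0
    n_clipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.midpoint_times)
        for name in (
            "ra_total", "rd_total", "ra_oral", "ra_endo", "hydroxylation",
            "synthesis_rate", "synthesis_g_day", "degradation_g_day",
            "net_gain_g_day",
        ):
            if len(getattr(self, name)) != n:
                raise GridError(f"KineticsResult.{name} length mismatch")
        self.validate()

    def validate(self, rtol: float = 1e-9) -> None:
        """Check Ra_total = Ra_endo + Ra_oral (+F per mode) where no flux was
        clipped to zero."""
        if sum(self.n_clipped.values()):
            return
        extra = self.tracer_rate if self.endo_mode == "subtract_tracer" else 0.0
        lhs = np.asarray(self.ra_total, dtype=float)
        rhs = np.asarray(self.ra_endo) + np.asarray(self.ra_oral) + extra
        scale = np.maximum(np.abs(lhs), 1e-30)
        if np.any(np.abs(lhs - rhs) / scale > rtol):
            raise DomainError("Ra_total != Ra_endo + Ra_oral (+F) beyond rtol")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "midpoint_time": self.midpoint_times,
                "ra_total": self.ra_total,
                "rd_total": self.rd_total,
                "ra_oral": self.ra_oral,
                "ra_endo": self.ra_endo,
                "hydroxylation": self.hydroxylation,
                "synthesis_rate": self.synthesis_rate,
                "synthesis_g_day": self.synthesis_g_day,
                "degradation_g_day": self.degradation_g_day,
                "net_gain_g_day": self.net_gain_g_day,
            }
        )


@dataclass
class AVBalanceResult:
    """Per-timepoint tissue balance for one analyte across one bed.

    In flow mode all quantities are μmol/min/kg LM; in difference mode
    ``net_balance`` is a plain arteriovenous concentration difference
    (μmol/L) and uptake/release/fractional extraction are NaN.
    """

    analyte: str
    time: np.ndarray
    net_balance: np.ndarray
    fractional_extraction: np.ndarray
    uptake: np.ndarray
    release: np.ndarray
    mode: str = "flow"

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("net_balance", "fractional_extraction", "uptake", "release"):
            if len(getattr(self, name)) != n:
                raise GridError(f"AVBalanceResult.{name} length mismatch")
        resid = self.uptake - self.net_balance - self.release
        ok = np.isfinite(resid)
        if np.any(resid[ok] != 0):
            raise DomainError("uptake - net_balance - release must be 0 exactly")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time": self.time,
                "net_balance": self.net_balance,
                "fractional_extraction": self.fractional_extraction,
                "uptake": self.uptake,
                "release": self.release,
            }
        )
        df.insert(0, "analyte", self.analyte)
        return df.melt(
            id_vars=["analyte", "time"], var_name="metric", value_name="value"
        )


@dataclass
class SimulationTruth:
    """Ground-truth profiles of one simulated subject-visit (dense grid)."""

    time: np.ndarray  # dense grid, covers −150…360 min
    ra_endo: np.ndarray
    ra_oral: np.ndarray
    rd: np.ndarray
    hydroxylation: np.ndarray
    ra_tyr_inflow: np.ndarray
    net_gain_g_day: np.ndarray
    muscle_fsr_percent_per_h: float
    plasma_fsr_percent_per_day: float
    av_time: np.ndarray
    av_profiles: dict[str, dict[str, np.ndarray]]  # analyte -> metric arrays
    seed: int
    noise: dict[str, float]
    #: channel -> (cumulative infused/produced, final pool, cumulative cleared)
    conservation: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def inflow(self) -> np.ndarray:
        """Total tracee inflow Ra_endo + Ra_oral (the quantity the Steele
        estimator targets)."""
        return self.ra_endo + self.ra_oral


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def effective_pool_volume(constants: Constants, subject: SubjectProfile) -> float:
    """Effective distribution volume per kg lean mass (L/kg LM).

    The pool fraction pV is tabulated per kg body weight while every flux is
    normalised per kg lean mass; multiplying by BW/LM puts the Steele pool
    term in the same units as the infusion rate.
    """
    if subject.lean_mass <= 0 or subject.body_weight <= 0:
        raise DomainError("body_weight and lean_mass must be positive")
    return constants.pool_fraction_pv * subject.body_weight / subject.lean_mass


def actual_infusion_rate(protocol: TracerProtocol, subject: SubjectProfile) -> float:
    """Realised tracer infusion rate, μmol/kg LM/min.

    Computed from the infusate concentration and the pump flow rate rather
    than the nominal protocol rate.
    """
    if subject.lean_mass <= 0:
        raise DomainError("lean_mass must be positive")
    return protocol.infusate_concentration * protocol.pump_flow / subject.lean_mass


def _channel_spec(channel: str) -> tuple[str, tuple[str, ...]]:
    try:
        return CHANNELS[channel]
    except KeyError:
        raise ConfigError(f"unknown enrichment channel {channel!r}") from None


def pooled_ttr(sample: PlasmaSample, channel: str) -> float:
    """Sum of a sample's isotopologue TTRs over the requested channel.

    Raises :class:`MissingDataError` naming the channel if any required
    isotopologue is absent or NaN.
    """
    analyte, isotopologues = _channel_spec(channel)
    if sample.analyte != analyte:
        raise MissingDataError(
            f"channel {channel!r} needs analyte {analyte!r}, "
            f"sample is {sample.analyte!r}"
        )
    total = 0.0
    for iso in isotopologues:
        value = sample.ttr.get(iso, math.nan)
        if math.isnan(value):
            raise MissingDataError(
                f"channel {channel!r}: isotopologue {iso!r} missing at "
                f"t={sample.time}"
            )
        total += value
    return total


def _pooled_ttr_or_nan(sample: PlasmaSample, channel: str) -> float:
    try:
        return pooled_ttr(sample, channel)
    except MissingDataError:
        return math.nan


def background_correct(
    series: PlasmaSeries,
    mode: str = "visit",
    background_time: float = BACKGROUND_TIME,
) -> PlasmaSeries:
    """Subtract natural-abundance (background) enrichment from all TTRs.

    mode="visit" (default) subtracts, per analyte and isotopologue, the TTR
    measured in the pre-prime sample at ``background_time`` from every later
    sample (clipped at zero), and drops the background sample from the
    returned series.  mode="none" returns the series unchanged (inputs
    already background-corrected).
    """
    if mode == "none":
        return series
    if mode != "visit":
        raise ConfigError(f"unknown background-correction mode {mode!r}")

    backgrounds: dict[tuple[str, str], float] = {}
    for s in series.samples:
        if s.time == background_time:
            for iso, value in s.ttr.items():
                backgrounds[(s.analyte, iso)] = value
    if not backgrounds:
        raise MissingDataError(
            f"no background sample at t={background_time} for site "
            f"{series.site!r}"
        )
    corrected = []
    for s in series.samples:
        if s.time == background_time:
            continue
        ttr = {
            iso: max(0.0, value - backgrounds.get((s.analyte, iso), 0.0))
            if not math.isnan(value)
            else value
            for iso, value in s.ttr.items()
        }
        corrected.append(replace(s, ttr=ttr))
    return PlasmaSeries(series.subject_id, series.visit, series.site, corrected)
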