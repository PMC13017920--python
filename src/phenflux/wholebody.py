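"""Whole-body non-steady-state isotope-dilution kinetics.

Single-pool (Steele) estimators evaluated on consecutive sample pairs with
midpoint timestamps: total and meal-derived (oral) phenylalanine rate of
appearance, rate of disappearance, phenylalanine hydroxylation via the
tyrosine system, protein synthesis/degradation/net gain, and the splanchnic
appearance percentage of the ingested meal label.

The estimator family assumes one rapidly mixing pool of effective volume
pV·BW/LM whose enrichment and concentration vary slowly between samples; the
time derivative is the finite difference across each pair and all pool terms
use pair means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .domain import (
    PHE,
    TYR,
    Constants,
    ConfigError,
    DegenerateEnrichmentError,
    GridError,
    KineticsResult,
    MealSpec,
    MissingDataError,
    PlasmaSeries,
    SubjectProfile,
    TracerProtocol,
    actual_infusion_rate,
    background_correct,
    effective_pool_volume,
)

logger = logging.getLogger("phenflux")

__all__ = [
    "SteelePair",
    "steele_ra",
    "steele_rd",
    "oral_ra",
    "endogenous_ra",
    "hydroxylation_rate",
    "protein_synthesis_rate",
    "to_grams_per_day",
    "net_protein_gain",
    "splanchnic_appearance_percent",
    "SplanchnicResult",
    "wholebody_pipeline",
]


@dataclass(frozen=True)
class SteelePair:
    """Concentration/enrichment at two consecutive sample times."""

    t1: float
    t2: float
    C1: float
    C2: float
    E1: float
    E2: float

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise GridError(f"require t2 > t1, got ({self.t1}, {self.t2})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t1 + self.t2)

    @property
    def mean_concentration(self) -> float:
        return 0.5 * (self.C1 + self.C2)

    @property
    def mean_enrichment(self) -> float:
        return 0.5 * (self.E1 + self.E2)

    @property
    def dEdt(self) -> float:
        return (self.E2 - self.E1) / (self.t2 - self.t1)

    @property
    def dCdt(self) -> float:
        return (self.C2 - self.C1) / (self.t2 - self.t1)


def steele_ra(F: float, pv_eff: float, pair: SteelePair) -> float:
    """Total rate of appearance, μmol/kg LM/min.

    Ra_total = (F − pV_eff · C̄ · dE/dt) / Ē.  At isotopic steady state this
    reduces to the classic dilution form F/E.
    """
    e_mean = pair.mean_enrichment
    if e_mean <= 0:
        raise DegenerateEnrichmentError(
            f"mean enrichment must be > 0 at midpoint {pair.midpoint}"
        )
    return (F - pv_eff * pair.mean_concentration * pair.dEdt) / e_mean


def steele_rd(ra_total: float, pv_eff: float, pair: SteelePair) -> float:
    """Rate of disappearance: Ra_total minus the pool-size change."""
    if pair.mean_enrichment <= 0:
        raise DegenerateEnrichmentError(
            f"mean enrichment must be > 0 at midpoint {pair.midpoint}"
        )
    return ra_total - pv_eff * pair.dCdt


def oral_ra(
    ra_total: float,
    pv_eff: float,
    d5_pair: SteelePair,
    meal: MealSpec,
    mode: str = "corrected",
) -> float:
    """Meal-derived (exogenous) phenylalanine appearance, μmol/kg LM/min.

    ``d5_pair`` carries the D5-phenylalanine (meal label) enrichment together
    with total phenylalanine concentration.  The label appearance
    Ra_total·Ē_D5 plus the change of label stored in the pool, divided by the
    meal labeling ratio r, yields the tracee-equivalent meal appearance.

    mode="corrected" (default) uses the dimensionally consistent pool term
    pV·C̄·dE/dt; mode="printed" reproduces the typeset literal form whose
    pool term omits the concentration factor.  Negative estimates are clipped
    to zero with a warning.
    """
    r = meal.d5_to_tracee_ratio_r
    if r <= 0:
        raise ConfigError("meal labeling ratio r must be positive")
    if mode == "corrected":
        pool_term = pv_eff * d5_pair.mean_concentration * d5_pair.dEdt
    elif mode == "printed":
        pool_term = pv_eff * d5_pair.dEdt
    else:
        raise ConfigError(f"unknown oral-Ra mode {mode!r}")
    value = (ra_total * d5_pair.mean_enrichment + pool_term) / r
    if value < 0:
        logger.warning(
            "oral Ra %.4g clipped to 0 at midpoint %s", value, d5_pair.midpoint
        )
        return 0.0
    return value


def endogenous_ra(
    ra_total: float, ra_oral: float, F: float = 0.0, mode: str = "simple"
) -> float:
    """Endogenous (proteolytic) appearance, μmol/kg LM/min.

    Phenylalanine is essential, so protein degradation is the only endogenous
    source.  mode="simple" (default): Ra_total − Ra_oral; mode
    "subtract_tracer" additionally removes the tracer infusion rate F.
    Negative results are clipped to zero with a warning.
    """
    if mode == "simple":
        value = ra_total - ra_oral
    elif mode == "subtract_tracer":
        value = ra_total - ra_oral - F
    else:
        raise ConfigError(f"unknown endogenous-Ra mode {mode!r}")
    if value < 0:
        logger.warning("endogenous Ra %.4g clipped to 0", value)
        return 0.0
    return value


def hydroxylation_rate(
    ra_tyr_d2: float, e_tyr_d7d6: float, e_phe_d8d7_pair: tuple[float, float]
) -> float:
    """Phenylalanine→tyrosine hydroxylation rate, μmol/kg LM/min.

    D7/D6-tyrosine appears only from hydroxylation of the infused (D8/D7)
    phenylalanine label, so its enrichment relative to the phenylalanine
    precursor enrichment scales the tyrosine appearance rate:
    hydrox = Ra_D2tyr · E_D7D6tyr / Ē_D8D7phe.
    """
    e1, e2 = e_phe_d8d7_pair
    e_phe = 0.5 * (e1 + e2)
    if e_phe <= 0:
        raise DegenerateEnrichmentError(
            "mean phenylalanine enrichment must be > 0"
        )
    return ra_tyr_d2 * e_tyr_d7d6 / e_phe


def protein_synthesis_rate(rd_total: float, hydroxylation: float) -> float:
    """Protein synthesis = Rd_total − hydroxylation (the only two removal
    pathways for phenylalanine).  A negative value is returned as-is but
    logged, since it signals noise larger than the flux."""
    value = rd_total - hydroxylation
    if value < 0:
        logger.warning("negative protein synthesis rate %.4g flagged", value)
    return value


def to_grams_per_day(rate: float, constants: Constants = Constants()) -> float:
    """Convert a phenylalanine flux (μmol/kg LM/min) to protein turnover
    (g protein/day/kg LM) via the average phenylalanine content of protein."""
    return rate * constants.minutes_per_day / constants.phe_per_gram_protein


def net_protein_gain(synthesis_g_day: float, degradation_g_day: float) -> float:
    """Net protein gain (g/day/kg LM); its negation is net protein loss."""
    return synthesis_g_day - degradation_g_day


@dataclass(frozen=True)
class SplanchnicResult:
    """Systemic appearance of the meal label and its complement."""

    appearance_percent: float
    first_pass_percent: float


def splanchnic_appearance_percent(
    midpoint_times: np.ndarray,
    oral_ra_series: np.ndarray,
    meal: MealSpec,
    subject: SubjectProfile,
    window: tuple[float, float] = (0.0, 360.0),
) -> SplanchnicResult:
    """AUC of oral Ra over the postprandial window as % of ingested phe.

    The oral-Ra midpoint series is anchored at zero appearance at meal time
    and held at its last value to the window end; the trapezoid AUC
    (μmol/kg LM) times lean mass is expressed as a percentage of the ingested
    amount.  The complement is reported as a first-pass splanchnic
    extraction estimate.
    """
    if meal.total_phe_ingested <= 0:
        raise ConfigError("total_phe_ingested must be positive")
    t0, t1 = window
    t = np.asarray(midpoint_times, dtype=float)
    y = np.asarray(oral_ra_series, dtype=float)
    keep = (t >= t0) & (t <= t1) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if t.size < 1:
        raise MissingDataError("no oral-Ra midpoints inside the AUC window")
    if t[0] > t0:
        t = np.insert(t, 0, t0)
        y = np.insert(y, 0, 0.0)
    if t[-1] < t1:
        t = np.append(t, t1)
        y = np.append(y, y[-1])
    auc = float(np.trapezoid(y, t))  # μmol/kg LM
    appearance = 100.0 * auc * subject.lean_mass / meal.total_phe_ingested
    return SplanchnicResult(appearance, 100.0 - appearance)


def postprandial_response(
    result: KineticsResult,
    window: tuple[float, float] = (15.0, 270.0),
    weight_window: tuple[float, float] = (0.0, 300.0),
) -> dict[str, float]:
    """Baseline-relative postprandial summaries of a kinetics result.

    Returns
    -------
    dict with
        ``endo_change_rel`` — weighted mean relative change of endogenous Ra
        (proteolysis) versus its −45 min fasting baseline over ``window``;
        negative under normal postprandial suppression.  Weights follow a
        raised-cosine over ``weight_window`` so mid-postprandial midpoints,
        where meal effects peak, dominate.
        ``net_gain_iauc`` — baseline-corrected incremental AUC of net protein
        gain over ``window``, g/kg LM.
    """
    from .indices import baseline_summary

    t = result.midpoint_times
    base_endo = baseline_summary(t, result.ra_endo, "kinetics")
    base_gain = baseline_summary(t, result.net_gain_g_day, "kinetics")
    m = (t >= window[0]) & (t <= window[1])
    w0, w1 = weight_window
    w = np.sin(np.pi * np.clip((t[m] - w0) / (w1 - w0), 0.0, 1.0)) ** 2
    if base_endo <= 0 or not np.any(w > 0):
        raise DegenerateEnrichmentError("degenerate baseline for response stats")
    endo_rel = float(np.sum(w * (result.ra_endo[m] - base_endo))
                     / (np.sum(w) * base_endo))
    gain_iauc = float(
        np.trapezoid(result.net_gain_g_day[m] - base_gain, t[m]) / 1440.0
    )
    return {"endo_change_rel": endo_rel, "net_gain_iauc": gain_iauc}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _paired(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return values[:-1], values[1:]


def wholebody_pipeline(
    arterial: PlasmaSeries,
    protocols: dict[str, TracerProtocol],
    meal: MealSpec,
    subject: SubjectProfile,
    constants: Constants = Constants(),
    oral_mode: str = "corrected",
    endo_mode: str = "simple",
    background: str = "visit",
    min_time: float = -60.0,
) -> KineticsResult:
    """Run the full whole-body calculus over consecutive arterial pairs.

    Requires phenylalanine concentration with D8+D7 and D5 channels and
    tyrosine concentration with D2 and D7+D6 channels.  Timepoints missing
    any required quantity are dropped, so pairs straddle gaps (a missing
    90-min sample yields the pair (60, 120) with midpoint 90).  The fasting
    baseline is the (−60, −30) pair at midpoint −45.
    """
    if "phe_d8" not in protocols or "tyr_d2" not in protocols:
        raise MissingDataError("protocols must include 'phe_d8' and 'tyr_d2'")

    series = background_correct(arterial, mode=background)
    pv_eff = effective_pool_volume(constants, subject)
    f_phe = actual_infusion_rate(protocols["phe_d8"], subject)
    f_tyr = actual_infusion_rate(protocols["tyr_d2"], subject)

    t_phe, c_phe = series.concentration_series(PHE)
    _, e_phe = series.channel_series("phe_d8d7")
    _, e_d5 = series.channel_series("phe_d5")
    t_tyr, c_tyr = series.concentration_series(TYR)
    _, e_d2 = series.channel_series("tyr_d2")
    _, e_d76 = series.channel_series("tyr_d7d6")

    if not np.array_equal(t_phe, t_tyr):
        raise GridError("phenylalanine and tyrosine sample grids differ")

    complete = (
        (t_phe >= min_time)
        & np.isfinite(c_phe) & np.isfinite(e_phe) & np.isfinite(e_d5)
        & np.isfinite(c_tyr) & np.isfinite(e_d2) & np.isfinite(e_d76)
    )
    t = t_phe[complete]
    if t.size < 2:
        raise GridError("need at least two complete timepoints")
    c_phe, e_phe, e_d5 = c_phe[complete], e_phe[complete], e_d5[complete]
    c_tyr, e_d2, e_d76 = c_tyr[complete], e_d2[complete], e_d76[complete]

    n_clipped = {"ra_oral": 0, "ra_endo": 0}
    rows = {k: [] for k in (
        "mid", "ra_total", "rd_total", "ra_oral", "ra_endo", "hydrox",
        "synthesis",
    )}
    for i in range(t.size - 1):
        phe_pair = SteelePair(t[i], t[i + 1], c_phe[i], c_phe[i + 1],
                              e_phe[i], e_phe[i + 1])
        tyr_pair = SteelePair(t[i], t[i + 1], c_tyr[i], c_tyr[i + 1],
                              e_d2[i], e_d2[i + 1])
        d5_pair = SteelePair(t[i], t[i + 1], c_phe[i], c_phe[i + 1],
                             e_d5[i], e_d5[i + 1])
        try:
            ra_tot = steele_ra(f_phe, pv_eff, phe_pair)
            rd_tot = steele_rd(ra_tot, pv_eff, phe_pair)
            ra_d2 = steele_ra(f_tyr, pv_eff, tyr_pair)
        except DegenerateEnrichmentError as exc:
            raise DegenerateEnrichmentError(
                f"{exc} (pair {t[i]}..{t[i + 1]} min)"
            ) from exc
        oral = oral_ra(ra_tot, pv_eff, d5_pair, meal, mode=oral_mode)
        if oral == 0.0 and (
            ra_tot * d5_pair.mean_enrichment
            + (pv_eff * d5_pair.mean_concentration * d5_pair.dEdt
               if oral_mode == "corrected" else pv_eff * d5_pair.dEdt)
        ) < 0:
            n_clipped["ra_oral"] += 1
        endo = endogenous_ra(ra_tot, oral, f_phe, mode=endo_mode)
        if endo == 0.0 and (
            (ra_tot - oral) if endo_mode == "simple"
            else (ra_tot - oral - f_phe)
        ) < 0:
            n_clipped["ra_endo"] += 1
        hydrox = hydroxylation_rate(
            ra_d2, 0.5 * (e_d76[i] + e_d76[i + 1]), (e_phe[i], e_phe[i + 1])
        )
        rows["mid"].append(phe_pair.midpoint)
        rows["ra_total"].append(ra_tot)
        rows["rd_total"].append(rd_tot)
        rows["ra_oral"].append(oral)
        rows["ra_endo"].append(endo)
        rows["hydrox"].append(hydrox)
        rows["synthesis"].append(protein_synthesis_rate(rd_tot, hydrox))

    synthesis = np.array(rows["synthesis"])
    endo = np.array(rows["ra_endo"])
    syn_g = np.array([to_grams_per_day(v, constants) for v in synthesis])
    deg_g = np.array([to_grams_per_day(v, constants) for v in endo])
    return KineticsResult(
        midpoint_times=np.array(rows["mid"]),
        ra_total=np.array(rows["ra_total"]),
        rd_total=np.array(rows["rd_total"]),
        ra_oral=np.array(rows["ra_oral"]),
        ra_endo=endo,
        hydroxylation=np.array(rows["hydrox"]),
        synthesis_rate=synthesis,
        synthesis_g_day=syn_g,
        degradation_g_day=deg_g,
        net_gain_g_day=syn_g - deg_g,
        endo_mode=endo_mode,
        tracer_rate=f_phe,
        n_clipped=n_clipped,
    )
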