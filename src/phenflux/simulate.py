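"""Forward simulator of the postprandial tracer study with known truth.

One rapidly mixing pool per amino acid (the same single-pool physiology the
Steele estimator assumes), driven by:

* endogenous phenylalanine appearance (proteolysis) with a smooth
  postprandial suppression bump,
* gamma-shaped absorption of meal phenylalanine (intrinsically D5-labeled
  casein) peaking near 40 min,
* primed-continuous D8-phenylalanine and D2-tyrosine infusions started at
  −150 min (prime as an instantaneous bolus),
* phenylalanine hydroxylation as a fixed fraction of phenylalanine Rd,
  feeding the tyrosine pool and producing the D7/D6-tyrosine label in
  proportion to the phenylalanine precursor enrichment,
* protein-bound label incorporation at the true muscle and plasma FSR,
* arteriovenous gradients across the leg (flow mode) and adipose bed
  (difference mode) built from true uptake/release/flow profiles,
* multiplicative lognormal measurement noise with per-quantity CVs and a
  natural-abundance background offset on every measured TTR (the −150
  pre-prime sample carries background only).

All tracer channels are cleared with the tracee's fractional rate constant;
clearance rate constants are fixed per subject at their fasting
steady-state values, so concentrations respond to inflow alone.  Every
quantity a downstream module estimates is recorded exactly in
:class:`~phenflux.domain.SimulationTruth`, enabling parameter-recovery
testing without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import gamma as _gamma_dist

from .domain import (
    BACKGROUND_TIME,
    GROUPS,
    PHE,
    STUDY_GRID,
    TYR,
    BiopsyEnrichment,
    BloodFlowSeries,
    ConfigError,
    MealSpec,
    PlasmaSample,
    PlasmaSeries,
    SimulationTruth,
    SubjectProfile,
    TracerProtocol,
)
from .indices import GlucoseInsulinProfile

__all__ = [
    "GroupPhysiology",
    "ScenarioConfig",
    "SyntheticDataset",
    "default_scenario",
    "simulate_subject",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupPhysiology:
    """True physiology of one study group (per-subject values are drawn
    around these).  Fluxes μmol/kg LM/min, concentrations μmol/L."""

    body_weight_mean: float
    body_weight_sd: float
    lean_fraction_mean: float
    lean_fraction_sd: float
    basal_phe_conc: float = 55.0
    basal_tyr_conc: float = 47.0
    conc_subject_cv: float = 0.05
    basal_ra_phe: float = 0.85
    basal_ra_phe_cv: float = 0.08
    suppression_depth: float = 0.30  # fractional proteolysis suppression
    suppression_depth_sd: float = 0.05
    suppression_onset: float = 0.0  # min
    suppression_duration: float = 300.0  # min
    hydrox_fraction: float = 0.05  # of phenylalanine Rd
    basal_ra_tyr: float = 0.50
    meal_systemic_fraction: float = 0.85  # of ingested phe appearing systemically
    absorption_shape: float = 3.0  # gamma shape (mode = (a-1)*scale = 40 min)
    absorption_scale: float = 20.0  # min
    fasting_glucose: float = 5.30  # mmol/L
    fasting_insulin: float = 31.6  # pmol/L
    glucose_rise: float = 2.2  # peak increment, mmol/L
    insulin_peak: float = 250.0  # pmol/L
    flow_basal: float = 0.35  # L/min
    flow_rise: float = 0.15
    leg_uptake_basal: float = 0.035  # phe, μmol/min/kg LM
    leg_uptake_rise: float = 0.045
    leg_release_basal: float = 0.055
    leg_release_suppression: float = 0.40
    tyr_av_scale: float = 0.6  # tyrosine AV profiles relative to phe
    adipose_phe_diff_rise: float = 2.0  # μmol/L postprandial a-v difference
    adipose_ala_diff: float = -5.0  # μmol/L (net release)
    ala_conc_basal: float = 250.0
    ala_conc_rise: float = 60.0
    muscle_fsr_percent_h: float = 0.08
    plasma_fsr_percent_day: float = 10.0
    muscle_free_dilution: float = 0.70  # muscle free pool TTR / plasma TTR


def _default_groups() -> dict[str, GroupPhysiology]:
    return {
        "healthy_weight": GroupPhysiology(
            body_weight_mean=75.4, body_weight_sd=5.4,
            lean_fraction_mean=0.77, lean_fraction_sd=0.03,
        ),
        "obesity": GroupPhysiology(
            body_weight_mean=111.8, body_weight_sd=12.1,
            lean_fraction_mean=0.61, lean_fraction_sd=0.04,
            basal_phe_conc=62.0, basal_tyr_conc=60.0,
            suppression_depth=0.25,
            fasting_glucose=5.67, fasting_insulin=89.8,
            glucose_rise=3.0, insulin_peak=450.0,
            flow_basal=0.45,
        ),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Full study scenario.  ``seed`` is mandatory: every random draw in the
    cohort is derived from it."""

    seed: int
    n_per_group: int = 12
    groups: dict[str, GroupPhysiology] = field(default_factory=_default_groups)
    visits: tuple[str, ...] = ("saline", "il6r_ab")
    #: multiplicative parameter shifts applied on the antibody visit
    visit_effects: dict[str, float] = field(
        default_factory=lambda: {
            "meal_systemic_fraction": 1.05,
            "hydrox_fraction": 1.10,
        }
    )
    casein_grams: float = 26.0
    meal_r: float = 0.02
    total_phe_ingested: float = 8190.0  # μmol (26 g casein × 315 μmol phe/g)
    phe_prime: float = 3.0  # μmol/kg LM
    phe_rate: float = 0.07  # μmol/kg LM/min
    phe_infusate_conc: float = 30.0  # μmol/mL
    tyr_prime: float = 2.3
    tyr_rate: float = 0.04
    tyr_infusate_conc: float = 24.0
    noise_cv_enrichment: float = 0.02
    noise_cv_concentration: float = 0.03
    noise_cv_flow: float = 0.05
    background_ttr: float = 0.001
    sampling_times: tuple[float, ...] = STUDY_GRID
    hormone_times: tuple[float, ...] = (0, 20, 30, 60, 90, 120)
    biopsy_times: tuple[float, float] = (-30.0, 360.0)
    plasma_protein_times: tuple[float, ...] = (-30.0, 60.0, 120.0, 240.0, 360.0)
    dense_step: float = 1.0  # min
    rtol: float = 1e-10
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")
        for g in self.groups.values():
            for name in ("suppression_depth", "hydrox_fraction",
                         "meal_systemic_fraction", "muscle_free_dilution",
                         "leg_release_suppression"):
                if not 0 <= getattr(g, name) <= 1:
                    raise ConfigError(f"{name} must lie in [0, 1]")


def default_scenario(seed: int, **overrides) -> ScenarioConfig:
    """The study-design scenario (two groups × two visits, n = 12/group)."""
    return ScenarioConfig(seed=seed, **overrides)


@dataclass
class SyntheticDataset:
    """Everything one subject-visit produces, plus the ground truth."""

    subject: SubjectProfile
    visit: str
    arterial: PlasmaSeries
    femoral: PlasmaSeries
    epigastric: PlasmaSeries
    flow: BloodFlowSeries
    biopsies: list[BiopsyEnrichment]
    plasma_protein_times: np.ndarray
    plasma_protein_ttr: np.ndarray
    plasma_protein_d5_ttr: np.ndarray  # meal-label-only channel
    glucose_insulin: GlucoseInsulinProfile
    meal: MealSpec
    protocols: dict[str, TracerProtocol]
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# Smooth profile primitives
# ---------------------------------------------------------------------------


def _gamma_pdf(t: float, shape: float, scale: float) -> float:
    if t <= 0.0:
        return 0.0
    return (
        t ** (shape - 1.0)
        * math.exp(-t / scale)
        / (math.gamma(shape) * scale**shape)
    )


def _raised_cosine(t: float, onset: float, duration: float) -> float:
    """C¹ bump: 0 outside [onset, onset+duration], peak 1 at the centre."""
    if t <= onset or t >= onset + duration:
        return 0.0
    return math.sin(math.pi * (t - onset) / duration) ** 2


def _norm_bump(t: float, peak_time: float) -> float:
    """Gamma-shape-2 bump normalised to peak 1 at ``peak_time``."""
    if t <= 0.0:
        return 0.0
    x = t / peak_time
    return x * math.exp(1.0 - x)


# ---------------------------------------------------------------------------
# Per-subject simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SubjectParams:
    body_weight: float
    lean_mass: float
    basal_phe_conc: float
    basal_tyr_conc: float
    basal_ra_phe: float
    suppression_depth: float
    phys: GroupPhysiology  # group physiology after visit shifts


def _apply_visit(phys: GroupPhysiology, visit: str,
                 effects: dict[str, float]) -> GroupPhysiology:
    if visit != "il6r_ab" or not effects:
        return phys
    changes = {
        name: getattr(phys, name) * factor for name, factor in effects.items()
    }
    return replace(phys, **changes)


def _draw_subject(phys: GroupPhysiology, rng: np.random.Generator) -> _SubjectParams:
    def tnorm(mean: float, sd: float) -> float:
        return mean + sd * float(np.clip(rng.standard_normal(), -2.5, 2.5))

    bw = max(tnorm(phys.body_weight_mean, phys.body_weight_sd), 40.0)
    lf = float(np.clip(tnorm(phys.lean_fraction_mean, phys.lean_fraction_sd),
                       0.35, 0.95))
    basal_ra = max(
        tnorm(phys.basal_ra_phe, phys.basal_ra_phe * phys.basal_ra_phe_cv), 0.2
    )
    depth = float(np.clip(
        tnorm(phys.suppression_depth, phys.suppression_depth_sd), 0.0, 0.90
    ))
    c_phe = phys.basal_phe_conc * (1 + phys.conc_subject_cv * float(
        np.clip(rng.standard_normal(), -2.5, 2.5)))
    c_tyr = phys.basal_tyr_conc * (1 + phys.conc_subject_cv * float(
        np.clip(rng.standard_normal(), -2.5, 2.5)))
    return _SubjectParams(bw, bw * lf, c_phe, c_tyr, basal_ra, depth, phys)


def _subject_rngs(
    config: ScenarioConfig, group: str, index: int, visit: str
) -> tuple[np.random.Generator, np.random.Generator]:
    """(parameter rng, noise rng): the parameter stream is visit-independent
    so a subject keeps one body across both visits; noise is per-visit."""
    gi = list(config.groups).index(group)
    vi = config.visits.index(visit) if visit in config.visits else 0
    param_ss = np.random.SeedSequence([int(config.seed), gi, int(index)])
    noise_ss = np.random.SeedSequence([int(config.seed), gi, int(index), vi, 1])
    return np.random.default_rng(param_ss), np.random.default_rng(noise_ss)


def simulate_subject(
    config: ScenarioConfig,
    subject_index: int = 0,
    group: str | None = None,
    visit: str = "saline",
) -> SyntheticDataset:
    """Simulate one subject-visit end-to-end.

    Deterministic in (config.seed, group, subject_index, visit): the same
    inputs reproduce bit-identical datasets.
    """
    if group is None:
        group = next(iter(config.groups))
    if group not in config.groups:
        raise ConfigError(f"unknown group {group!r}")
    param_rng, rng = _subject_rngs(config, group, subject_index, visit)
    phys = _apply_visit(config.groups[group], visit, config.visit_effects)
    params = _draw_subject(phys, param_rng)
    subject = SubjectProfile(
        subject_id=f"{group[:3]}{subject_index:02d}",
        group=group,
        body_weight=round(params.body_weight, 3),
        lean_mass=round(params.lean_mass, 3),
        visit=visit,
    )

    meal = MealSpec(
        casein_grams=config.casein_grams,
        d5_to_tracee_ratio_r=config.meal_r,
        total_phe_ingested=config.total_phe_ingested,
    )
    lm = subject.lean_mass
    protocols = {
        "phe_d8": TracerProtocol(
            "phe_d8", config.phe_prime, config.phe_rate,
            config.phe_infusate_conc,
            config.phe_rate * lm / config.phe_infusate_conc,
        ),
        "tyr_d2": TracerProtocol(
            "tyr_d2", config.tyr_prime, config.tyr_rate,
            config.tyr_infusate_conc,
            config.tyr_rate * lm / config.tyr_infusate_conc,
        ),
    }

    # --- pool parameters (fasting steady state fixes the rate constants) ---
    v_pool = 0.125 * subject.body_weight / lm  # L/kg LM
    c0_phe, c0_tyr = params.basal_phe_conc, params.basal_tyr_conc
    k_phe = params.basal_ra_phe / (v_pool * c0_phe)
    hyd_basal = phys.hydrox_fraction * params.basal_ra_phe
    k_tyr = (phys.basal_ra_tyr + hyd_basal) / (v_pool * c0_tyr)
    f_phe, f_tyr = config.phe_rate, config.tyr_rate
    a_oral = (
        config.total_phe_ingested * phys.meal_systemic_fraction / lm
    )
    r_meal = config.meal_r
    shape, scale = phys.absorption_shape, phys.absorption_scale
    depth = params.suppression_depth
    onset, dur = phys.suppression_onset, phys.suppression_duration
    basal_ra = params.basal_ra_phe
    ra_tyr_endo = phys.basal_ra_tyr
    hfrac = phys.hydrox_fraction
    fsr_m = phys.muscle_fsr_percent_h / 100.0 / 60.0  # fraction per min
    fsr_p = phys.plasma_fsr_percent_day / 100.0 / 1440.0
    dil = phys.muscle_free_dilution

    def ra_endo_fn(t: float) -> float:
        return basal_ra * (1.0 - depth * _raised_cosine(t, onset, dur))

    def ra_oral_fn(t: float) -> float:
        return a_oral * _gamma_pdf(t, shape, scale)

    # state: C, c8, c5, Ct, c2, c76, cleared(8,5,2,76), prod76, Em, Ep, Ep5
    def rhs(t, y):
        C, c8, c5, Ct, c2, c76 = y[0], y[1], y[2], y[3], y[4], y[5]
        endo, oral = ra_endo_fn(t), ra_oral_fn(t)
        hyd = hfrac * k_phe * v_pool * C
        e8 = c8 / C
        e_all = (c8 + c5) / C
        return [
            (endo + oral - k_phe * v_pool * C) / v_pool,
            (f_phe - k_phe * v_pool * c8) / v_pool,
            (r_meal * oral - k_phe * v_pool * c5) / v_pool,
            (ra_tyr_endo + hyd - k_tyr * v_pool * Ct) / v_pool,
            (f_tyr - k_tyr * v_pool * c2) / v_pool,
            (hyd * e8 - k_tyr * v_pool * c76) / v_pool,
            k_phe * v_pool * c8,
            k_phe * v_pool * c5,
            k_tyr * v_pool * c2,
            k_tyr * v_pool * c76,
            hyd * e8,
            fsr_m * dil * e_all,
            fsr_p * e_all,
            fsr_p * (c5 / C),
        ]

    t0, t1 = float(BACKGROUND_TIME), float(max(config.sampling_times))
    y0 = [
        c0_phe, config.phe_prime / v_pool, 0.0,
        c0_tyr, config.tyr_prime / v_pool, 0.0,
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
    ]
    dense_t = np.arange(t0, t1 + 0.5 * config.dense_step, config.dense_step)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA", t_eval=dense_t,
        rtol=config.rtol, atol=config.atol, max_step=5.0,
    )
    if not sol.success or np.any(sol.y[:6] < -1e-9):
        raise ConfigError(
            "unstable simulation (negative pool); check basal rates, "
            "suppression depth and absorption parameters"
        )
    sol.y[:6] = np.clip(sol.y[:6], 0.0, None)  # solver noise around zero
    C, c8, c5, Ct, c2, c76 = sol.y[:6]
    cl8, cl5, cl2, cl76, prod76, em, ep, ep5 = sol.y[6:]

    # ------------------------------------------------------------- truth --
    endo_d = np.array([ra_endo_fn(t) for t in dense_t])
    oral_d = np.array([ra_oral_fn(t) for t in dense_t])
    rd_d = k_phe * v_pool * C
    hyd_d = hfrac * rd_d
    syn_g = (rd_d - hyd_d) * 1440.0 / 273.0
    deg_g = endo_d * 1440.0 / 273.0

    sample_times = np.array(
        [t for t in config.sampling_times if t > BACKGROUND_TIME], dtype=float
    )
    bump = np.array([_norm_bump(t, 60.0) for t in sample_times])
    q_true = phys.flow_basal + phys.flow_rise * bump
    supp = np.array([_raised_cosine(t, onset, dur) for t in sample_times])
    av_true: dict[str, dict[str, np.ndarray]] = {}
    up_phe = phys.leg_uptake_basal + phys.leg_uptake_rise * bump
    rel_phe = phys.leg_release_basal * (1.0 - phys.leg_release_suppression * supp)
    av_true[PHE] = {"uptake": up_phe, "release": rel_phe,
                    "net_balance": up_phe - rel_phe, "flow": q_true}
    s = phys.tyr_av_scale
    av_true[TYR] = {"uptake": s * up_phe, "release": s * rel_phe,
                    "net_balance": s * (up_phe - rel_phe), "flow": q_true}
    av_true["adipose_phenylalanine"] = {
        "difference": phys.adipose_phe_diff_rise * bump
    }
    av_true["adipose_alanine"] = {
        "difference": np.full(sample_times.shape, phys.adipose_ala_diff)
    }

    # tracer balances at end of study (channel -> infused, pool, cleared)
    elapsed = t1 - t0
    gamma_cdf = float(_gamma_dist.cdf(t1, shape, scale=scale))
    conservation = {
        "phe_d8": (config.phe_prime + f_phe * elapsed,
                   v_pool * c8[-1], cl8[-1]),
        "phe_d5": (r_meal * a_oral * gamma_cdf, v_pool * c5[-1], cl5[-1]),
        "tyr_d2": (config.tyr_prime + f_tyr * elapsed,
                   v_pool * c2[-1], cl2[-1]),
        "tyr_d7d6": (prod76[-1], v_pool * c76[-1], cl76[-1]),
    }

    truth = SimulationTruth(
        time=dense_t,
        ra_endo=endo_d,
        ra_oral=oral_d,
        rd=rd_d,
        hydroxylation=hyd_d,
        ra_tyr_inflow=ra_tyr_endo + hyd_d,
        net_gain_g_day=syn_g - deg_g,
        muscle_fsr_percent_per_h=phys.muscle_fsr_percent_h,
        plasma_fsr_percent_per_day=phys.plasma_fsr_percent_day,
        av_time=sample_times,
        av_profiles=av_true,
        seed=int(config.seed),
        noise={
            "enrichment": config.noise_cv_enrichment,
            "concentration": config.noise_cv_concentration,
            "flow": config.noise_cv_flow,
        },
        conservation=conservation,
    )

    # -------------------------------------------------------- measurement --
    def noisy(x: float, cv: float) -> float:
        if cv <= 0:
            return float(x)
        return float(x * math.exp(cv * rng.standard_normal()))

    cv_e = config.noise_cv_enrichment
    cv_c = config.noise_cv_concentration
    bg = config.background_ttr

    def interp(arr: np.ndarray, t: float) -> float:
        return float(np.interp(t, dense_t, arr))

    # lumped channels are split into individual isotopologues on output
    d8_split, d76_split = (0.92, 0.08), (0.60, 0.40)

    def phe_ttrs(e8_lump: float, e5: float) -> dict[str, float]:
        return {
            "d8": noisy(d8_split[0] * e8_lump + bg, cv_e),
            "d7": noisy(d8_split[1] * e8_lump + bg, cv_e),
            "d5": noisy(e5 + bg, cv_e),
        }

    def tyr_ttrs(e2: float, e76_lump: float) -> dict[str, float]:
        return {
            "d2": noisy(e2 + bg, cv_e),
            "d7": noisy(d76_split[0] * e76_lump + bg, cv_e),
            "d6": noisy(d76_split[1] * e76_lump + bg, cv_e),
        }

    def background_sample(site: str, analyte: str, conc: float,
                          isotopologues: tuple[str, ...]) -> PlasmaSample:
        return PlasmaSample(
            time=float(BACKGROUND_TIME), site=site, analyte=analyte,
            concentration=noisy(conc, cv_c),
            ttr={iso: noisy(bg, cv_e) if bg > 0 else 0.0
                 for iso in isotopologues},
        )

    ala_conc = np.array(
        [phys.ala_conc_basal + phys.ala_conc_rise * _norm_bump(t, 45.0)
         for t in sample_times]
    )

    def make_arterial() -> PlasmaSeries:
        samples = [
            background_sample("artery", PHE, c0_phe, ("d8", "d7", "d5")),
            background_sample("artery", TYR, c0_tyr, ("d2", "d7", "d6")),
            background_sample("artery", "alanine", phys.ala_conc_basal, ()),
        ]
        for i, t in enumerate(sample_times):
            cphe, ctyr = interp(C, t), interp(Ct, t)
            samples.append(PlasmaSample(
                time=t, site="artery", analyte=PHE,
                concentration=noisy(cphe, cv_c),
                ttr=phe_ttrs(interp(c8, t) / cphe, interp(c5, t) / cphe),
            ))
            samples.append(PlasmaSample(
                time=t, site="artery", analyte=TYR,
                concentration=noisy(ctyr, cv_c),
                ttr=tyr_ttrs(interp(c2, t) / ctyr, interp(c76, t) / ctyr),
            ))
            samples.append(PlasmaSample(
                time=t, site="artery", analyte="alanine",
                concentration=noisy(ala_conc[i], cv_c),
            ))
        return PlasmaSeries(subject.subject_id, visit, "artery", samples)

    def venous_state(analyte: str, i: int, t: float):
        """True venous concentration and channel extraction at one time."""
        prof = av_true[analyte]
        if analyte == PHE:
            ca, ch = interp(C, t), {"lump8": interp(c8, t), "d5": interp(c5, t)}
        else:
            ca, ch = interp(Ct, t), {"d2": interp(c2, t),
                                     "lump76": interp(c76, t)}
        q = q_true[i]
        cv_conc = ca - prof["net_balance"][i] * lm / q
        fe = prof["uptake"][i] * lm / (ca * q)
        if cv_conc <= 0 or not 0 <= fe <= 1:
            raise ConfigError(
                f"AV scenario infeasible for {analyte} at t={t}: "
                f"Cv={cv_conc:.3g}, FE={fe:.3g}"
            )
        factor = (1.0 - fe) * ca / cv_conc  # venous/arterial TTR ratio
        return cv_conc, {k: (v / ca) * factor for k, v in ch.items()}

    def make_femoral() -> PlasmaSeries:
        samples = [
            background_sample("femoral_vein", PHE, c0_phe, ("d8", "d7", "d5")),
            background_sample("femoral_vein", TYR, c0_tyr, ("d2", "d7", "d6")),
            background_sample("femoral_vein", "alanine", phys.ala_conc_basal, ()),
        ]
        for i, t in enumerate(sample_times):
            cvp, ep_ch = venous_state(PHE, i, t)
            samples.append(PlasmaSample(
                time=t, site="femoral_vein", analyte=PHE,
                concentration=noisy(cvp, cv_c),
                ttr=phe_ttrs(ep_ch["lump8"], ep_ch["d5"]),
            ))
            cvt, et_ch = venous_state(TYR, i, t)
            samples.append(PlasmaSample(
                time=t, site="femoral_vein", analyte=TYR,
                concentration=noisy(cvt, cv_c),
                ttr=tyr_ttrs(et_ch["d2"], et_ch["lump76"]),
            ))
            # alanine: concentration-only net release from the leg
            samples.append(PlasmaSample(
                time=t, site="femoral_vein", analyte="alanine",
                concentration=noisy(ala_conc[i] + 8.0, cv_c),
            ))
        return PlasmaSeries(subject.subject_id, visit, "femoral_vein", samples)

    def make_epigastric() -> PlasmaSeries:
        """Adipose bed: difference mode (no flow), small uptake gradients."""
        samples = []
        for i, t in enumerate(sample_times):
            bump_t = _norm_bump(t, 60.0)
            diff_phe = phys.adipose_phe_diff_rise * bump_t
            cphe = interp(C, t)
            samples.append(PlasmaSample(
                time=t, site="epigastric_vein", analyte=PHE,
                concentration=noisy(cphe - diff_phe, cv_c),
            ))
            samples.append(PlasmaSample(
                time=t, site="epigastric_vein", analyte="alanine",
                concentration=noisy(ala_conc[i] - phys.adipose_ala_diff, cv_c),
            ))
        return PlasmaSeries(subject.subject_id, visit, "epigastric_vein", samples)

    flow = BloodFlowSeries(
        time=sample_times,
        flow=np.array(
            [noisy(q, config.noise_cv_flow) for q in q_true], dtype=float
        ),
    )

    biopsies = [
        BiopsyEnrichment(
            time=float(t),
            protein_bound_ttr=noisy(interp(em, t), cv_e),
            free_pool_ttr=noisy(
                dil * (interp(c8, t) + interp(c5, t)) / interp(C, t), cv_e
            ),
        )
        for t in config.biopsy_times
    ]
    pp_times = np.array(config.plasma_protein_times, dtype=float)
    pp_ttr = np.array(
        [noisy(interp(ep, t), cv_e) for t in pp_times], dtype=float
    )
    pp_d5_ttr = np.array(
        [noisy(interp(ep5, t), cv_e) for t in pp_times], dtype=float
    )

    h_t = np.array(config.hormone_times, dtype=float)
    g0, i0 = phys.fasting_glucose, phys.fasting_insulin
    glucose = np.array(
        [noisy(g0 + phys.glucose_rise * _norm_bump(t, 40.0), cv_c)
         for t in h_t]
    )
    insulin = np.array(
        [noisy(i0 + (phys.insulin_peak - i0) * _norm_bump(t, 40.0), cv_c)
         for t in h_t]
    )
    gi = GlucoseInsulinProfile(
        fasting_glucose=g0, fasting_insulin=i0,
        times=h_t, glucose=glucose, insulin=insulin,
    )

    return SyntheticDataset(
        subject=subject, visit=visit,
        arterial=make_arterial(), femoral=make_femoral(),
        epigastric=make_epigastric(), flow=flow,
        biopsies=biopsies,
        plasma_protein_times=pp_times, plasma_protein_ttr=pp_ttr,
        plasma_protein_d5_ttr=pp_d5_ttr,
        glucose_insulin=gi, meal=meal, protocols=protocols, truth=truth,
    )


def simulate_cohort(config: ScenarioConfig) -> list[SyntheticDataset]:
    """Simulate every subject of every group and visit (independent draws)."""
    datasets = []
    for group in config.groups:
        for index in range(config.n_per_group):
            for visit in config.visits:
                datasets.append(
                    simulate_subject(config, index, group=group, visit=visit)
                )
    return datasets
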