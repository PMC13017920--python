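"""Two-pool arteriovenous balance across a tissue bed.

Leg balances (femoral vein, with Doppler femoral arterial flow) are computed
in flow mode and reported per minute per kg lean mass; abdominal subcutaneous
adipose tissue (superficial epigastric vein, no reliable flow measure) uses
difference mode, reporting plain arteriovenous concentration differences.

For an essential amino acid like phenylalanine the two-pool interpretation
is: uptake ≈ tissue protein synthesis, release ≈ tissue protein degradation,
net balance ≈ net tissue protein balance.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .domain import (
    BACKGROUND_TIME,
    AVBalanceResult,
    AlignmentError,
    BloodFlowSeries,
    ConfigError,
    DegenerateEnrichmentError,
    DomainError,
    MissingDataError,
    PlasmaSeries,
    SubjectProfile,
    background_correct,
)

__all__ = [
    "AVSamplePair",
    "net_balance",
    "fractional_extraction",
    "uptake",
    "release",
    "av_pipeline",
]


@dataclass(frozen=True)
class AVSamplePair:
    """Simultaneous arterial/venous measurements of one analyte."""

    time: float
    Ca: float
    Cv: float
    Ea: float = math.nan  # arterial TTR (optional)
    Ev: float = math.nan  # venous TTR (optional)
    flow: float = math.nan  # L/min (optional)
    lean_mass: float = math.nan  # kg

    def __post_init__(self) -> None:
        if self.Ca < 0 or self.Cv < 0:
            raise DomainError("concentrations must be >= 0")
        if not math.isnan(self.flow) and self.flow <= 0:
            raise DomainError("blood flow must be > 0 when present")


def net_balance(pair: AVSamplePair, mode: str = "flow") -> float:
    """Net tissue balance (positive = net uptake).

    flow mode: (Ca − Cv) × flow / LM, μmol/min/kg LM.
    difference mode: Ca − Cv, μmol/L (adipose bed, no flow available).
    """
    if mode == "difference":
        return pair.Ca - pair.Cv
    if mode != "flow":
        raise ConfigError(f"unknown net-balance mode {mode!r}")
    if math.isnan(pair.flow):
        raise MissingDataError(f"flow required in flow mode at t={pair.time}")
    if math.isnan(pair.lean_mass) or pair.lean_mass <= 0:
        raise MissingDataError("lean_mass required in flow mode")
    return (pair.Ca - pair.Cv) * pair.flow / pair.lean_mass


def fractional_extraction(pair: AVSamplePair) -> float:
    """Fraction of the arterial tracer inflow removed by the bed:
    FE = (Ca·Ea − Cv·Ev) / (Ca·Ea)."""
    arterial_flux = pair.Ca * pair.Ea
    if math.isnan(arterial_flux) or arterial_flux <= 0:
        raise DegenerateEnrichmentError(
            f"arterial tracer flux Ca*Ea must be > 0 at t={pair.time}"
        )
    return (arterial_flux - pair.Cv * pair.Ev) / arterial_flux


def uptake(fe: float, pair: AVSamplePair) -> float:
    """Tracer-derived unidirectional uptake = FE × Ca × flow / LM."""
    if math.isnan(pair.flow):
        raise MissingDataError(f"flow required for uptake at t={pair.time}")
    if math.isnan(pair.lean_mass) or pair.lean_mass <= 0:
        raise MissingDataError("lean_mass required for uptake")
    return fe * pair.Ca * pair.flow / pair.lean_mass


def release(uptake_value: float, net_balance_value: float) -> float:
    """Release = uptake − net balance (two-pool closure)."""
    return uptake_value - net_balance_value


def _drop_background(series: PlasmaSeries) -> PlasmaSeries:
    kept = [s for s in series.samples if s.time != BACKGROUND_TIME]
    if len(kept) == len(series.samples):
        return series
    return PlasmaSeries(series.subject_id, series.visit, series.site, kept)


def av_pipeline(
    arterial: PlasmaSeries,
    venous: PlasmaSeries,
    flow: BloodFlowSeries | None,
    subject: SubjectProfile,
    mode: str = "flow",
    analytes: list[str] | None = None,
    enrichment_channels: dict[str, str] | None = None,
    background: str = "visit",
) -> dict[str, AVBalanceResult]:
    """Per-timepoint balance metrics for every analyte present at both sites.

    Flow is linearly interpolated to the blood-sample times when the grids
    differ.  ``enrichment_channels`` maps analyte -> channel name for
    analytes with tracer data (default: phenylalanine D8+D7, tyrosine D2);
    analytes without enrichments get net balance only (uptake/release NaN).
    In difference mode no flow is needed and only concentration differences
    are produced.

    In flow mode both series are background-corrected first (``background=
    "none"`` if inputs already are); the pre-prime background sample is
    always excluded from the balance grid.
    """
    if mode not in ("flow", "difference"):
        raise ConfigError(f"unknown AV mode {mode!r}")
    if mode == "flow" and flow is None:
        raise MissingDataError("flow series required in flow mode")
    if mode == "flow" and background != "none":
        arterial = background_correct(arterial, mode=background)
        venous = background_correct(venous, mode=background)
    else:
        arterial = _drop_background(arterial)
        venous = _drop_background(venous)
    if enrichment_channels is None:
        enrichment_channels = {
            "phenylalanine": "phe_d8d7",
            "tyrosine": "tyr_d2",
        }
    if analytes is None:
        analytes = sorted(set(arterial.analytes()) & set(venous.analytes()))
        if not analytes:
            raise AlignmentError("no common analytes between sites")

    results: dict[str, AVBalanceResult] = {}
    for analyte in analytes:
        t_a, c_a = arterial.concentration_series(analyte)
        t_v, c_v = venous.concentration_series(analyte)
        if not np.array_equal(t_a, t_v):
            offending = sorted(set(t_a.tolist()) ^ set(t_v.tolist()))
            raise AlignmentError(
                f"arterial/venous grids differ for {analyte!r} at times "
                f"{offending}"
            )
        channel = enrichment_channels.get(analyte)
        if channel is not None and mode == "flow":
            _, e_a = arterial.channel_series(channel)
            _, e_v = venous.channel_series(channel)
        else:
            e_a = np.full_like(c_a, math.nan)
            e_v = np.full_like(c_v, math.nan)
        q = flow.at(t_a) if (flow is not None and mode == "flow") else (
            np.full_like(t_a, math.nan)
        )

        nb = np.empty_like(c_a)
        fe = np.full_like(c_a, math.nan)
        up = np.full_like(c_a, math.nan)
        rel = np.full_like(c_a, math.nan)
        for i, time in enumerate(t_a):
            pair = AVSamplePair(
                time=time, Ca=c_a[i], Cv=c_v[i], Ea=e_a[i], Ev=e_v[i],
                flow=q[i], lean_mass=subject.lean_mass,
            )
            nb[i] = net_balance(pair, mode=mode)
            if mode == "flow" and not math.isnan(e_a[i]):
                fe[i] = fractional_extraction(pair)
                up[i] = uptake(fe[i], pair)
                rel[i] = release(up[i], nb[i])
        results[analyte] = AVBalanceResult(
            analyte=analyte, time=t_a, net_balance=nb,
            fractional_extraction=fe, uptake=up, release=rel, mode=mode,
        )
    return results
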