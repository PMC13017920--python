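"""CSV bundle readers and writers.

A *study bundle* is a directory of tidy CSV tables plus a ``manifest.yaml``:

========================  ====================================================
file                      columns
========================  ====================================================
subjects.csv              subject_id, visit, group, body_weight, lean_mass
meal.csv                  casein_grams, d5_to_tracee_ratio_r,
                          total_phe_ingested, energy_kcal, volume_ml,
                          ingestion_time
protocols.csv             subject_id, visit, tracer_id, prime,
                          continuous_rate_nominal, infusate_concentration,
                          pump_flow
plasma.csv                subject_id, visit, site, time, analyte,
                          concentration, ttr_d2, ttr_d5, ttr_d6, ttr_d7,
                          ttr_d8
flow.csv                  subject_id, visit, time, flow
biopsies.csv              subject_id, visit, time, protein_bound_ttr,
                          free_pool_ttr
plasma_protein.csv        subject_id, visit, time, protein_ttr,
                          protein_ttr_d5
hormones.csv              subject_id, visit, time, analyte, value
truth_profiles.csv (opt)  subject_id, visit, time, ra_endo, ra_oral, rd,
                          hydroxylation, net_gain_g_day
truth_scalars.csv (opt)   per subject-visit scalar truths
========================  ====================================================

Times are minutes relative to the meal; all numeric output is written at six
significant digits, which is the comparison precision for determinism.
Empty cells denote missing values and are read back as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .domain import (
    BiopsyEnrichment,
    BloodFlowSeries,
    GridError,
    MealSpec,
    MissingDataError,
    PlasmaSample,
    PlasmaSeries,
    SubjectProfile,
    TracerProtocol,
)
from .indices import GlucoseInsulinProfile
from .simulate import SyntheticDataset

SCHEMA_VERSION = 1
FLOAT_FORMAT = "%.6g"
_TTR_COLUMNS = ("ttr_d2", "ttr_d5", "ttr_d6", "ttr_d7", "ttr_d8")

__all__ = ["StudyBundle", "SubjectVisitData", "write_bundle", "read_bundle"]


@dataclass
class SubjectVisitData:
    """All validated inputs for one subject at one visit."""

    subject: SubjectProfile
    visit: str
    plasma: dict[str, PlasmaSeries]
    flow: BloodFlowSeries | None
    biopsies: list[BiopsyEnrichment]
    plasma_protein_times: np.ndarray
    plasma_protein_ttr: np.ndarray
    plasma_protein_d5_ttr: np.ndarray
    glucose_insulin: GlucoseInsulinProfile | None
    protocols: dict[str, TracerProtocol]


@dataclass
class StudyBundle:
    path: Path
    schema_version: int
    meal: MealSpec
    records: dict[tuple[str, str], SubjectVisitData] = field(default_factory=dict)

    def keys(self):
        return self.records.keys()

    def __getitem__(self, key: tuple[str, str]) -> SubjectVisitData:
        return self.records[key]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_bundle(
    datasets: list[SyntheticDataset], outdir: str | Path, truth: bool = True
) -> Path:
    """Write a list of simulated subject-visits as a study bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    subjects, plasma, flow, biopsies, pp, hormones, protocols = (
        [], [], [], [], [], [], []
    )
    truth_profiles, truth_scalars, truth_av, truth_cons = [], [], [], []
    for ds in datasets:
        key = dict(subject_id=ds.subject.subject_id, visit=ds.visit)
        subjects.append({**key, "group": ds.subject.group,
                         "body_weight": ds.subject.body_weight,
                         "lean_mass": ds.subject.lean_mass})
        for proto in ds.protocols.values():
            protocols.append({**key, "tracer_id": proto.tracer_id,
                              "prime": proto.prime,
                              "continuous_rate_nominal":
                                  proto.continuous_rate_nominal,
                              "infusate_concentration":
                                  proto.infusate_concentration,
                              "pump_flow": proto.pump_flow})
        for series in (ds.arterial, ds.femoral, ds.epigastric):
            for s in series.samples:
                row = {**key, "site": s.site, "time": s.time,
                       "analyte": s.analyte, "concentration": s.concentration}
                for col in _TTR_COLUMNS:
                    row[col] = s.ttr.get(col.removeprefix("ttr_"), math.nan)
                plasma.append(row)
        for t, q in zip(ds.flow.time, ds.flow.flow):
            flow.append({**key, "time": t, "flow": q})
        for b in ds.biopsies:
            biopsies.append({**key, "time": b.time,
                             "protein_bound_ttr": b.protein_bound_ttr,
                             "free_pool_ttr": b.free_pool_ttr})
        for t, e, e5 in zip(ds.plasma_protein_times, ds.plasma_protein_ttr,
                            ds.plasma_protein_d5_ttr):
            pp.append({**key, "time": t, "protein_ttr": e,
                       "protein_ttr_d5": e5})
        gi = ds.glucose_insulin
        hormones.append({**key, "time": -30.0, "analyte": "glucose",
                         "value": gi.fasting_glucose})
        hormones.append({**key, "time": -30.0, "analyte": "insulin",
                         "value": gi.fasting_insulin})
        for t, g, i in zip(gi.times, gi.glucose, gi.insulin):
            hormones.append({**key, "time": t, "analyte": "glucose", "value": g})
            hormones.append({**key, "time": t, "analyte": "insulin", "value": i})
        if truth:
            tr = ds.truth
            for j, t in enumerate(tr.time):
                truth_profiles.append({
                    **key, "time": t, "ra_endo": tr.ra_endo[j],
                    "ra_oral": tr.ra_oral[j], "rd": tr.rd[j],
                    "hydroxylation": tr.hydroxylation[j],
                    "net_gain_g_day": tr.net_gain_g_day[j],
                })
            truth_scalars.append({
                **key,
                "muscle_fsr_percent_per_h": tr.muscle_fsr_percent_per_h,
                "plasma_fsr_percent_per_day": tr.plasma_fsr_percent_per_day,
                "seed": tr.seed,
            })
            for analyte, metrics in tr.av_profiles.items():
                for metric, values in metrics.items():
                    for t, v in zip(tr.av_time, values):
                        truth_av.append({**key, "analyte": analyte,
                                         "time": t, "metric": metric,
                                         "value": v})
            for channel, (inf, pool, cleared) in tr.conservation.items():
                truth_cons.append({**key, "channel": channel,
                                   "infused": inf, "pool": pool,
                                   "cleared": cleared})

    meal = datasets[0].meal
    _write_csv(pd.DataFrame(subjects), outdir / "subjects.csv")
    _write_csv(pd.DataFrame([{
        "casein_grams": meal.casein_grams,
        "d5_to_tracee_ratio_r": meal.d5_to_tracee_ratio_r,
        "total_phe_ingested": meal.total_phe_ingested,
        "energy_kcal": meal.energy_kcal,
        "volume_ml": meal.volume_ml,
        "ingestion_time": meal.ingestion_time,
    }]), outdir / "meal.csv")
    _write_csv(pd.DataFrame(protocols), outdir / "protocols.csv")
    _write_csv(pd.DataFrame(plasma), outdir / "plasma.csv")
    _write_csv(pd.DataFrame(flow), outdir / "flow.csv")
    _write_csv(pd.DataFrame(biopsies), outdir / "biopsies.csv")
    _write_csv(pd.DataFrame(pp), outdir / "plasma_protein.csv")
    _write_csv(pd.DataFrame(hormones), outdir / "hormones.csv")
    files = ["subjects.csv", "meal.csv", "protocols.csv", "plasma.csv",
             "flow.csv", "biopsies.csv", "plasma_protein.csv", "hormones.csv"]
    if truth:
        _write_csv(pd.DataFrame(truth_profiles), outdir / "truth_profiles.csv")
        _write_csv(pd.DataFrame(truth_scalars), outdir / "truth_scalars.csv")
        _write_csv(pd.DataFrame(truth_av), outdir / "truth_av.csv")
        _write_csv(pd.DataFrame(truth_cons), outdir / "truth_conservation.csv")
        files += ["truth_profiles.csv", "truth_scalars.csv", "truth_av.csv",
                  "truth_conservation.csv"]
    manifest = {"schema_version": SCHEMA_VERSION, "files": sorted(files)}
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True)
    )
    return outdir


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _require(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise MissingDataError(f"bundle file missing: {path.name}")
    return pd.read_csv(path)


def read_bundle(path: str | Path) -> StudyBundle:
    """Read and validate a study bundle directory.

    Type invariants (positive masses, strictly increasing times, known site
    labels) are enforced by the domain constructors; violations surface as
    the corresponding domain errors with file context.
    """
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise MissingDataError(f"no manifest.yaml in {path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise MissingDataError(f"unrecognized schema version {version!r}")

    meal_row = _require(path / "meal.csv").iloc[0]
    meal = MealSpec(
        casein_grams=float(meal_row["casein_grams"]),
        d5_to_tracee_ratio_r=float(meal_row["d5_to_tracee_ratio_r"]),
        total_phe_ingested=float(meal_row["total_phe_ingested"]),
        energy_kcal=float(meal_row["energy_kcal"]),
        volume_ml=float(meal_row["volume_ml"]),
        ingestion_time=float(meal_row["ingestion_time"]),
    )
    subjects_df = _require(path / "subjects.csv")
    protocols_df = _require(path / "protocols.csv")
    plasma_df = _require(path / "plasma.csv")
    flow_df = _require(path / "flow.csv")
    biopsies_df = _require(path / "biopsies.csv")
    pp_df = _require(path / "plasma_protein.csv")
    hormones_df = _require(path / "hormones.csv")

    bundle = StudyBundle(path=path, schema_version=version, meal=meal)
    for _, row in subjects_df.iterrows():
        sid, visit = str(row["subject_id"]), str(row["visit"])
        subject = SubjectProfile(
            subject_id=sid, group=str(row["group"]),
            body_weight=float(row["body_weight"]),
            lean_mass=float(row["lean_mass"]), visit=visit,
        )
        sel = lambda df: df[(df["subject_id"] == sid) & (df["visit"] == visit)]

        protocols = {}
        for _, p in sel(protocols_df).iterrows():
            protocols[str(p["tracer_id"])] = TracerProtocol(
                tracer_id=str(p["tracer_id"]), prime=float(p["prime"]),
                continuous_rate_nominal=float(p["continuous_rate_nominal"]),
                infusate_concentration=float(p["infusate_concentration"]),
                pump_flow=float(p["pump_flow"]),
            )

        plasma: dict[str, PlasmaSeries] = {}
        sub_plasma = sel(plasma_df)
        for site in sub_plasma["site"].unique():
            rows = sub_plasma[sub_plasma["site"] == site]
            samples = []
            for _, s in rows.iterrows():
                ttr = {
                    col.removeprefix("ttr_"): float(s[col])
                    for col in _TTR_COLUMNS
                    if col in s and not pd.isna(s[col])
                }
                samples.append(PlasmaSample(
                    time=float(s["time"]), site=str(site),
                    analyte=str(s["analyte"]),
                    concentration=float(s["concentration"])
                    if not pd.isna(s["concentration"]) else math.nan,
                    ttr=ttr,
                ))
            try:
                plasma[str(site)] = PlasmaSeries(sid, visit, str(site), samples)
            except GridError as exc:
                raise GridError(f"plasma.csv [{sid}/{visit}/{site}]: {exc}")

        fl = sel(flow_df).sort_values("time")
        flow = (
            BloodFlowSeries(fl["time"].to_numpy(float),
                            fl["flow"].to_numpy(float))
            if len(fl) else None
        )
        biopsies = [
            BiopsyEnrichment(
                time=float(b["time"]),
                protein_bound_ttr=float(b["protein_bound_ttr"]),
                free_pool_ttr=float(b["free_pool_ttr"]),
            )
            for _, b in sel(biopsies_df).sort_values("time").iterrows()
        ]
        pp_rows = sel(pp_df).sort_values("time")
        horm = sel(hormones_df)
        gi = None
        if len(horm):
            fasting = horm[horm["time"] == -30.0]
            post = horm[(horm["time"] >= 0) & (horm["time"] <= 120)]
            g = post[post["analyte"] == "glucose"].sort_values("time")
            i = post[post["analyte"] == "insulin"].sort_values("time")
            if len(fasting) and len(g) and np.array_equal(
                g["time"].to_numpy(), i["time"].to_numpy()
            ):
                gi = GlucoseInsulinProfile(
                    fasting_glucose=float(
                        fasting[fasting["analyte"] == "glucose"]["value"].iloc[0]
                    ),
                    fasting_insulin=float(
                        fasting[fasting["analyte"] == "insulin"]["value"].iloc[0]
                    ),
                    times=g["time"].to_numpy(float),
                    glucose=g["value"].to_numpy(float),
                    insulin=i["value"].to_numpy(float),
                )
        bundle.records[(sid, visit)] = SubjectVisitData(
            subject=subject, visit=visit, plasma=plasma, flow=flow,
            biopsies=biopsies,
            plasma_protein_times=pp_rows["time"].to_numpy(float),
            plasma_protein_ttr=pp_rows["protein_ttr"].to_numpy(float),
            plasma_protein_d5_ttr=(
                pp_rows["protein_ttr_d5"].to_numpy(float)
                if "protein_ttr_d5" in pp_rows else
                np.full(len(pp_rows), math.nan)
            ),
            glucose_insulin=gi, protocols=protocols,
        )
    return bundle
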