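"""End-to-end orchestration: cohort → geometry → virtual splenectomy →
hemodynamics → ALWSS → statistics.

`run_patient` turns one patient's sampled anatomy into a postoperative
ALWSS score; `run_cohort` maps it over a synthetic cohort, draws
thrombosis labels from the configured logistic risk model on the true
scores, and produces the evaluation report (ROC/AUC, accuracy-optimal
ALWSS threshold, correlations of ALWSS with SV diameter and PV velocity,
Mood's median tests per covariate, per-anatomy-type ALWSS summaries).

Clinical-unit conversion happens at the config boundary (mmHg, cm/s, mm
in; SI inside; cm² out for areas).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    CohortPatient,
    DistributionSpec,
    generate_labels,
    sample_cohort,
)
from .errors import ConfigError
from .geometry import apply_splenectomy, build_tree, distance_metric
from .hemodynamics import (
    DEFAULT_FLOW_SPLIT,
    DEFAULT_OUTLET_PRESSURE_PA,
    MMHG_TO_PA,
    BoundaryConditions,
    FlowSplit,
    assign_inlet_flows,
    compute_wss_field,
    solve_flows,
)
from .rheology import CarreauParams
from .stats import moods_median_test, pearson_r, roc_auc
from .wss_metrics import DEFAULT_LOW_WSS_FRACTION, MetricsResult, compute_metrics

log = logging.getLogger("portalwss.pipeline")

#: Fixed dimensions of the vessels the cohort model does not sample
#: (diameter, length, tortuosity — SI units). Config-overridable.
DEFAULT_FIXED_VESSELS: dict[str, tuple[float, float, float]] = {
    "PV": (float("nan"), 0.060, 1.05),  # diameter sampled per patient
    "SMV": (0.010, 0.080, 1.10),
    "LGV": (0.005, 0.040, 1.20),
    "IMV": (0.005, 0.060, 1.10),
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (one reproducible run)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_csv: str | None = None
    carreau: CarreauParams = field(default_factory=CarreauParams)
    outlet_pressure_mmhg: float = DEFAULT_OUTLET_PRESSURE_PA / MMHG_TO_PA
    flow_split: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLOW_SPLIT)
    )
    flow_mode: str = "subtract_sv"
    stump_model: str = "stasis"
    dx: float = 1.0e-3  # m
    low_wss_fraction: float = DEFAULT_LOW_WSS_FRACTION
    fixed_vessels: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_VESSELS)
    )
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = _as_jsonable(self)
        payload.pop("out_dir", None)  # where results land is not what they are
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @staticmethod
    def from_dict(raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict = {}
        if "cohort" in raw:
            c = dict(raw.pop("cohort"))
            if "distributions" in c:
                c["distributions"] = {
                    k: DistributionSpec(**v) for k, v in c["distributions"].items()
                }
            if "anatomy_probabilities" in c:
                c["anatomy_probabilities"] = tuple(c["anatomy_probabilities"])
            kwargs["cohort"] = CohortConfig(**c)
        if "carreau" in raw:
            kwargs["carreau"] = CarreauParams(**raw.pop("carreau"))
        if "fixed_vessels" in raw:
            kwargs["fixed_vessels"] = {
                k: tuple(v) for k, v in raw.pop("fixed_vessels").items()
            }
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return RunConfig(**kwargs)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------
# per-patient pipeline
# ---------------------------------------------------------------------


def patient_tree(patient: CohortPatient, cfg: RunConfig):
    """Preoperative portal tree for one patient's sampled anatomy."""
    diameters, lengths, torts = {}, {}, {}
    for name, (d, length, tort) in cfg.fixed_vessels.items():
        diameters[name], lengths[name], torts[name] = d, length, tort
    diameters["PV"] = patient.pv_diameter
    diameters["SV"] = patient.sv_diameter
    lengths["SV"] = patient.sv_length
    torts["SV"] = patient.sv_tortuosity
    return build_tree(
        diameters, lengths, torts, anatomy_type=patient.anatomy_type
    )


def run_patient(patient: CohortPatient, cfg: RunConfig) -> MetricsResult:
    """Postoperative ALWSS metrics for a single patient."""
    try:
        tree = patient_tree(patient, cfg)
        post = apply_splenectomy(tree)
        bc = BoundaryConditions(
            pv_velocity=patient.pv_velocity,
            outlet_pressure=cfg.outlet_pressure_mmhg * MMHG_TO_PA,
            flow_split=FlowSplit(cfg.flow_split),
            flow_mode=cfg.flow_mode,
        )
        inlet_flows = assign_inlet_flows(post, bc)
        flows = solve_flows(post, inlet_flows)
        field_ = compute_wss_field(
            post, flows, cfg.carreau, cfg.dx, stump_model=cfg.stump_model
        )
        metrics = compute_metrics(field_, cfg.low_wss_fraction)
    except Exception as exc:
        raise type(exc)(f"patient {patient.id}: {exc}") from exc
    log.debug(
        "patient=%s inlet_flows=%s mean_wss=%.6g threshold=%.6g alwss=%.6g",
        patient.id,
        {k: f"{v:.4g}" for k, v in inlet_flows.items()},
        metrics.mean_wss,
        metrics.threshold,
        metrics.alwss,
    )
    return metrics


# ---------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------

COHORT_CSV_COLUMNS = [
    "id",
    "anatomy_type",
    "pv_velocity_m_s",
    "pv_diameter_m",
    "sv_diameter_m",
    "sv_length_m",
    "sv_tortuosity",
    "sv_distance_m",
    "spleen_max_diameter_m",
    "mean_wss_pa",
    "threshold_pa",
    "alwss_cm2",
    "total_area_cm2",
    "label",
]


@dataclass(frozen=True)
class CohortRunResult:
    metrics: pd.DataFrame
    statistics: dict


def load_cohort_csv(path: str | Path) -> list[CohortPatient]:
    df = pd.read_csv(path)
    return [
        CohortPatient(
            id=str(row["id"]),
            pv_velocity=row["pv_velocity_m_s"],
            pv_diameter=row["pv_diameter_m"],
            sv_diameter=row["sv_diameter_m"],
            sv_length=row["sv_length_m"],
            sv_tortuosity=row["sv_tortuosity"],
            anatomy_type=int(row["anatomy_type"]),
            spleen_max_diameter=row["spleen_max_diameter_m"],
            label=int(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else None,
        )
        for _, row in df.iterrows()
    ]


def cohort_to_frame(
    patients: Sequence[CohortPatient],
    metrics: Sequence[MetricsResult] | None = None,
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(patients):
        row = {
            "id": p.id,
            "anatomy_type": p.anatomy_type,
            "pv_velocity_m_s": p.pv_velocity,
            "pv_diameter_m": p.pv_diameter,
            "sv_diameter_m": p.sv_diameter,
            "sv_length_m": p.sv_length,
            "sv_tortuosity": p.sv_tortuosity,
            "sv_distance_m": p.sv_length / p.sv_tortuosity,
            "spleen_max_diameter_m": p.spleen_max_diameter,
        }
        if metrics is not None:
            m = metrics[i]
            row.update(
                mean_wss_pa=m.mean_wss,
                threshold_pa=m.threshold,
                alwss_cm2=m.alwss,
                total_area_cm2=m.total_area,
            )
        if labels is not None:
            row["label"] = int(labels[i])
        elif p.label is not None:
            row["label"] = p.label
        rows.append(row)
    return pd.DataFrame(rows)


def _label_seed(seed: int) -> int:
    # decorrelate the label stream from the covariate stream
    return (seed * 2654435761 + 9973) % (2**31)


def cohort_statistics(df: pd.DataFrame) -> dict:
    """Evaluation statistics from a metrics table with labels."""
    stats: dict = {}
    labels = df["label"].to_numpy(dtype=int)
    scores = df["alwss_cm2"].to_numpy(dtype=float)
    if len(df) < 2 or len(np.unique(labels)) < 2:
        log.warning("fewer than 2 patients or single-class labels: statistics skipped")
        return {"skipped": "fewer than 2 patients or single-class labels"}
    roc = roc_auc(scores, labels)
    stats["roc"] = {
        "auc": roc.auc,
        "best_threshold_cm2": roc.best_threshold,
        "correctly_classified_ratio": roc.correctly_classified_ratio,
        "points": [list(p) for p in roc.points],
    }
    for key, col in [
        ("alwss_vs_sv_diameter", "sv_diameter_m"),
        ("alwss_vs_pv_velocity", "pv_velocity_m_s"),
    ]:
        r, p = pearson_r(df[col], scores)
        stats.setdefault("correlations", {})[key] = {"r": r, "p": p}
    stats["moods_median_tests"] = {}
    for col in [
        "pv_velocity_m_s",
        "pv_diameter_m",
        "sv_diameter_m",
        "sv_length_m",
        "sv_distance_m",
        "spleen_max_diameter_m",
        "alwss_cm2",
    ]:
        g1 = df.loc[labels == 0, col].to_numpy(dtype=float)
        g2 = df.loc[labels == 1, col].to_numpy(dtype=float)
        try:
            chi2, p = moods_median_test(g1, g2)
            stats["moods_median_tests"][col] = {
                "chi2": chi2,
                "p": p,
                "median_no_thrombosis": float(np.median(g1)),
                "median_thrombosis": float(np.median(g2)),
            }
        except Exception as exc:  # degenerate group split
            stats["moods_median_tests"][col] = {"skipped": str(exc)}
    by_type = {}
    for t, sub in df.groupby("anatomy_type"):
        vals = sub["alwss_cm2"].to_numpy(dtype=float)
        by_type[int(t)] = {
            "n": int(len(vals)),
            "mean_alwss_cm2": float(np.mean(vals)),
            "se_alwss_cm2": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1
            else None,
        }
    stats["alwss_by_anatomy_type"] = by_type
    return stats


def run_cohort(cfg: RunConfig) -> CohortRunResult:
    """Run the full pipeline on a synthetic (or CSV-loaded) cohort."""
    if cfg.cohort_csv is not None:
        patients = load_cohort_csv(cfg.cohort_csv)
    else:
        patients = sample_cohort(
            dataclasses.replace(cfg.cohort, seed=cfg.seed)
        )
    log.info("running %d patients (stump=%s, flow=%s)", len(patients),
             cfg.stump_model, cfg.flow_mode)
    metrics = [run_patient(p, cfg) for p in patients]
    alwss_values = [m.alwss for m in metrics]
    if all(p.label is not None for p in patients):
        labels = [int(p.label) for p in patients]
    else:
        labels = generate_labels(
            alwss_values, cfg.cohort.beta0, cfg.cohort.beta1, _label_seed(cfg.seed)
        ).tolist()
    df = cohort_to_frame(patients, metrics, labels)
    stats = cohort_statistics(df)
    report = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_patients": len(patients),
        "flow_split": dict(cfg.flow_split),
        "flow_mode": cfg.flow_mode,
        "stump_model": cfg.stump_model,
        "statistics": stats,
    }
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "cohort_metrics.csv", index=False)
        (out / "statistics.json").write_text(json.dumps(report, indent=2) + "\n")
        log.info("wrote %s and %s", out / "cohort_metrics.csv", out / "statistics.json")
    return CohortRunResult(metrics=df, statistics=report)
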