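"""End-to-end analysis: cohort -> features -> cutoffs -> survival -> report.

The pipeline mirrors the structure of a prognostic biomarker study report:

1. subgroup summaries — per clinical subgroup, the median and range of each
   spectral feature with a Mann-Whitney comparison between the two arms;
2. group mean and difference spectra (complete remission minus
   relapse/progression) of tumour-at-biopsy spectra;
3. ROC analysis with cost-weighted cutoff selection per spectral feature
   (t_b, shift_tt_tb, shift_tb_tn) against the unfavourable-outcome label
   (progression, relapse or death during follow-up);
4. Kaplan-Meier / log-rank univariate comparisons of PFS and OS for every
   clinical factor and every dichotomised spectral feature, with survival
   evaluated at the configured horizon (default 36 months);
5. Cox proportional-hazards models of PFS: the full model and the
   backward-Wald-eliminated model;

plus rank correlations of percent necrosis against each feature.  Every
table cell carries the number of patients actually used after missing-data
drops.  Reports are deterministic given identical inputs and seed;
timestamps live in a separate metadata file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import stats as st
from . import survival as surv
from .io import PatientRecord, Spectrum, load_cohort
from .preprocess import PreprocessConfig, preprocess

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "analyze_cohort", "write_report"]

# printed direction of each dichotomisation rule: which tail is high-risk
FEATURE_ORIENTATIONS = {
    "t_b": st.HIGHER,
    "shift_tt_tb": st.LOWER,
    "shift_tb_tn": st.HIGHER,
}

REPORT_SECTIONS = (
    "config",
    "cohort",
    "features",
    "group_summaries",
    "difference_spectrum",
    "cutoffs",
    "univariate",
    "km_curves",
    "cox",
    "correlations",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    manifest_path: str | None = None
    clinical_path: str | None = None
    out_dir: str = "ftirsurv_report"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    apex_mode: str = "grid"
    aggregate: str = "positions"
    agg_method: str = "mean"
    reporting_resolution: float | None = 1.0
    cost_ratio: float = 2.0
    prevalence_weighting: bool = True
    auto_orientation: bool = False
    ties: str = "efron"
    alpha_remove: float = 0.10
    horizon_months: float = 36.0
    age_split_years: float = 15.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pp = d.pop("preprocess", {})
        if isinstance(pp, dict):
            if "analysis_band" in pp:
                pp["analysis_band"] = tuple(pp["analysis_band"])
            pp = PreprocessConfig(**pp)
        return cls(preprocess=pp, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# helpers


def _unfavourable_labels(records: Sequence[PatientRecord]) -> dict[str, int | None]:
    """1 if the patient progressed, relapsed or died during follow-up."""
    out = {}
    for r in records:
        if r.pfs_event is None and r.os_event is None:
            out[r.patient_id] = None
        else:
            out[r.patient_id] = int(bool(r.pfs_event) or bool(r.os_event))
    return out


def _subgroup_splits(records: Sequence[PatientRecord], config: RunConfig):
    """Two-arm clinical splits used for subgroup summaries and log-rank tests."""
    a = config.age_split_years

    def split(name, arms):
        return (name, arms)

    return [
        split("gender", {"male": lambda r: r.gender == "male",
                         "female": lambda r: r.gender == "female"}),
        split("age", {f"<{a:g}": lambda r: r.age_years is not None and r.age_years < a,
                      f">={a:g}": lambda r: r.age_years is not None and r.age_years >= a}),
        split("disease", {"local": lambda r: r.disease_extent == "local",
                          "metastatic": lambda r: r.disease_extent == "metastatic"}),
        split("site", {"peripheral": lambda r: r.site == "peripheral",
                       "axial/pelvis": lambda r: r.site == "axial"}),
        split("necrosis", {
            "favorable(>=90%)": lambda r: r.necrosis_pct is not None and r.necrosis_pct >= 90,
            "unfavorable(<90%)": lambda r: r.necrosis_pct is not None and r.necrosis_pct < 90}),
        split("radiotherapy", {"yes": lambda r: r.radiotherapy == 1,
                               "no": lambda r: r.radiotherapy == 0}),
        split("auto_hsct", {"yes": lambda r: r.auto_hsct == 1,
                            "no": lambda r: r.auto_hsct == 0}),
        split("adjuvant_ctx", {"VAI": lambda r: r.adjuvant_ctx == "VAI",
                               "VAC": lambda r: r.adjuvant_ctx == "VAC"}),
    ]


def _outcome_splits(records: Sequence[PatientRecord]):
    return [
        ("relapse/progression", {"yes": lambda r: r.pfs_event == 1,
                                 "no": lambda r: r.pfs_event == 0}),
        ("death", {"yes": lambda r: r.os_event == 1,
                   "no": lambda r: r.os_event == 0}),
    ]


def _feature_values(features, name) -> dict[str, float]:
    return {f.patient_id: f.get(name) for f in features if f.get(name) is not None}


def _median_range(values: list[float]) -> dict:
    if not values:
        return {"n": 0, "median": None, "min": None, "max": None}
    arr = np.asarray(values, dtype=float)
    return {
        "n": int(arr.size),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


# ---------------------------------------------------------------------------
# stages


def _stage_group_summaries(records, features, config) -> list[dict]:
    rows = []
    splits = _subgroup_splits(records, config) + _outcome_splits(records)
    for fname in feat.FEATURE_NAMES:
        vals = _feature_values(features, fname)
        for varname, arms in splits:
            arm_items = list(arms.items())
            arm_values = {}
            for arm_name, pred in arm_items:
                ids = [r.patient_id for r in records if pred(r)]
                arm_values[arm_name] = [vals[i] for i in ids if i in vals]
            p = None
            v0, v1 = (arm_values[a] for a, _ in arm_items)
            if v0 and v1 and len(set(v0 + v1)) > 1:
                _, p = st.mann_whitney(v0, v1)
            for arm_name, _ in arm_items:
                rows.append(
                    {
                        "feature": fname,
                        "variable": varname,
                        "subgroup": arm_name,
                        **_median_range(arm_values[arm_name]),
                        "mann_whitney_p": p,
                    }
                )
        rows.append(
            {
                "feature": fname,
                "variable": "total",
                "subgroup": "all",
                **_median_range(list(vals.values())),
                "mann_whitney_p": None,
            }
        )
    return rows


def _stage_difference_spectrum(records, spectra, config):
    """Mean preprocessed t_b spectrum per outcome group and their difference.

    Convention: (complete remission mean) - (relapse/progression mean).
    """
    labels = _unfavourable_labels(records)
    remission, relapse = [], []
    for s in spectra:
        if s.tissue_type != "t_b" or labels.get(s.patient_id) is None:
            continue
        target = relapse if labels[s.patient_id] else remission
        target.append(preprocess(s, config.preprocess))
    out: dict = {"orientation": "remission_minus_relapse", "n_remission": len(remission),
                 "n_relapse": len(relapse)}
    if remission and relapse:
        mean_rem = feat.group_mean_spectrum(remission)
        mean_rel = feat.group_mean_spectrum(relapse)
        diff = feat.difference_spectrum(mean_rem, mean_rel)
        out["wavenumbers"] = mean_rem.wavenumbers.tolist()
        out["mean_remission"] = mean_rem.absorbance.tolist()
        out["mean_relapse"] = mean_rel.absorbance.tolist()
        out["difference"] = diff.absorbance.tolist()
    return out


def _stage_cutoffs(records, features, config) -> dict:
    labels = _unfavourable_labels(records)
    out = {}
    for fname, orientation in FEATURE_ORIENTATIONS.items():
        vals = _feature_values(features, fname)
        pairs = [(v, labels[pid]) for pid, v in vals.items() if labels.get(pid) is not None]
        n_dropped = sum(1 for f in features if f.get(fname) is None)
        if not pairs:
            out[fname] = {"error": "no usable values", "n_dropped_missing": n_dropped}
            continue
        scores = [p[0] for p in pairs]
        labs = [p[1] for p in pairs]
        if config.auto_orientation:
            roc = st.roc_curve(scores, labs, st.HIGHER)
            if roc.auc < 0.5:
                roc = st.roc_curve(scores, labs, st.LOWER)
        else:
            roc = st.roc_curve(scores, labs, orientation)
        spec = st.select_cutoff(
            roc,
            cost_ratio=config.cost_ratio,
            prevalence_weighting=config.prevalence_weighting,
            feature=fname,
        )
        out[fname] = {
            "rule": spec.rule_text(),
            "threshold": spec.threshold,
            "direction": spec.direction,
            "orientation": roc.orientation,
            "auc": roc.auc,
            "sensitivity": spec.sensitivity,
            "specificity": spec.specificity,
            "expected_cost": spec.expected_cost,
            "cost_ratio": spec.cost_ratio,
            "prevalence_weighting": spec.prevalence_weighting,
            "n_used": len(pairs),
            "n_dropped_missing": n_dropped,
            "roc": {
                "thresholds": roc.thresholds.tolist(),
                "sensitivity": roc.sensitivity.tolist(),
                "specificity": roc.specificity.tolist(),
            },
            "_spec": spec,
        }
    return out


def _km_arm(records_subset, endpoint, horizon):
    times = [getattr(r, f"{endpoint}_months") for r in records_subset]
    events = [getattr(r, f"{endpoint}_event") for r in records_subset]
    keep = [(t, e) for t, e in zip(times, events) if t is not None and e is not None]
    if not keep:
        return None, None, None
    t, e = zip(*keep)
    curve = surv.km_estimate(t, e)
    return curve, surv.survival_at(curve, horizon), (list(t), list(e))


def _stage_univariate(records, features, cutoffs, config) -> tuple[list[dict], dict]:
    rows = []
    km_tables: dict[str, dict] = {}
    by_id = {r.patient_id: r for r in records}

    def compare(varname, arm_defs):
        arms = {}
        for arm_name, ids in arm_defs.items():
            subset = [by_id[i] for i in ids]
            arms[arm_name] = subset
        row = {"variable": varname}
        for endpoint in ("pfs", "os"):
            curves, data = {}, {}
            for arm_name, subset in arms.items():
                curve, at_h, td = _km_arm(subset, endpoint, config.horizon_months)
                curves[arm_name] = (curve, at_h)
                data[arm_name] = td
                if curve is not None:
                    km_tables.setdefault(f"{varname}|{endpoint}", {})[arm_name] = (
                        curve.to_frame().to_dict(orient="records")
                    )
            names = list(arms)
            for arm_name in names:
                row[f"n_{arm_name}"] = len(arms[arm_name])
                row[f"{endpoint}_{config.horizon_months:g}m_{arm_name}"] = curves[arm_name][1]
            p = None
            td0, td1 = data[names[0]], data[names[1]]
            if td0 and td1 and (sum(td0[1]) + sum(td1[1]) > 0):
                try:
                    _, p = surv.logrank_test(td0[0], td0[1], td1[0], td1[1])
                except ValueError:
                    p = None
            row[f"{endpoint}_logrank_p"] = p
        rows.append(row)

    for varname, arms in _subgroup_splits(records, config):
        arm_defs = {
            arm: [r.patient_id for r in records if pred(r)] for arm, pred in arms.items()
        }
        compare(varname, arm_defs)

    for fname, info in cutoffs.items():
        spec = info.get("_spec")
        if spec is None:
            continue
        groups = st.dichotomize(features, spec)
        high = [pid for pid, g in groups.items() if g == 1]
        low = [pid for pid, g in groups.items() if g == 0]
        op = ">=" if spec.direction == "ge" else "<"
        inverse = "<" if spec.direction == "ge" else ">="
        compare(
            f"{fname} {op} {spec.threshold:g}",
            {
                f"{fname}{op}{spec.threshold:g}": high,
                f"{fname}{inverse}{spec.threshold:g}": low,
            },
        )
    return rows, km_tables


def _stage_cox(records, features, cutoffs, config) -> dict:
    """Cox PFS models on male gender plus the three dichotomised features."""
    by_id = {r.patient_id: r for r in records}
    cols: dict[str, dict[str, float]] = {}
    cols["male_gender"] = {
        r.patient_id: float(r.gender == "male") for r in records if r.gender is not None
    }
    for fname, info in cutoffs.items():
        spec = info.get("_spec")
        if spec is None:
            continue
        groups = st.dichotomize(features, spec)
        op = ">=" if spec.direction == "ge" else "<"
        colname = f"{fname}{op}{spec.threshold:g}"
        cols[colname] = {pid: float(g) for pid, g in groups.items() if g is not None}

    ids = [r.patient_id for r in records
           if r.pfs_months is not None and r.pfs_event is not None]
    complete = [i for i in ids if all(i in c for c in cols.values())]
    n_dropped = len(ids) - len(complete)
    X = pd.DataFrame({name: [c[i] for i in complete] for name, c in cols.items()},
                     index=complete)
    times = [by_id[i].pfs_months for i in complete]
    events = [by_id[i].pfs_event for i in complete]

    def model_dict(m: surv.CoxModel) -> dict:
        return {
            "covariates": list(m.covariates),
            "beta": m.beta.tolist(),
            "se": m.se.tolist(),
            "wald_p": m.wald_p.tolist(),
            "hr": m.hr.tolist(),
            "ci_lower": m.ci_lower.tolist(),
            "ci_upper": m.ci_upper.tolist(),
            "model_p": m.model_p,
            "loglik": m.loglik,
            "n": m.n,
            "n_events": m.n_events,
            "ties": m.ties,
            "separation": list(m.separation),
        }

    out = {"n_complete": len(complete), "n_dropped_missing": n_dropped}
    try:
        full = surv.cox_fit(X, times, events, ties=config.ties)
        selected = surv.backward_wald(X, times, events,
                                      alpha_remove=config.alpha_remove, ties=config.ties)
        out["full_model"] = model_dict(full)
        out["backward_wald"] = model_dict(selected)
        out["elimination_trace"] = [
            {"removed": name, "wald_p": p} for name, p in selected.elimination_trace
        ]
    except (ValueError, RuntimeError) as exc:
        logger.warning("Cox stage degraded: %s", exc)
        out["error"] = str(exc)
    return out


def _stage_correlations(records, features) -> dict:
    """Spearman rank correlation of percent necrosis with each feature."""
    out = {}
    by_id = {r.patient_id: r for r in records}
    for fname in feat.FEATURE_NAMES:
        pairs = [
            (by_id[f.patient_id].necrosis_pct, f.get(fname))
            for f in features
            if f.get(fname) is not None
            and by_id[f.patient_id].necrosis_pct is not None
        ]
        if len(pairs) < 3:
            out[fname] = {"n": len(pairs), "rho": None, "p": None}
            continue
        x, y = zip(*pairs)
        try:
            rho, p = st.spearman(x, y)
        except ValueError:
            rho, p = None, None
        out[fname] = {"n": len(pairs), "rho": rho, "p": p}
    return out


# ---------------------------------------------------------------------------
# orchestration


def analyze_cohort(
    records: Sequence[PatientRecord],
    spectra: Sequence[Spectrum],
    config: RunConfig | None = None,
) -> dict:
    """Run the full analysis on an in-memory cohort and return the report."""
    config = config or RunConfig()
    report: dict = {"config": config.to_dict()}

    stage = "features"
    try:
        processed = [preprocess(s, config.preprocess) for s in spectra]
        features = feat.compute_patient_features(
            processed,
            band=config.preprocess.analysis_band,
            config=config.preprocess,
            apex_mode=config.apex_mode,
            aggregate=config.aggregate,
            agg_method=config.agg_method,
            resolution=config.reporting_resolution,
            preprocessed=True,
        )
        tn_missing = sum(1 for f in features if f.t_n is None)
        report["cohort"] = {
            "n_patients": len(records),
            "n_with_features": len(features),
            "n_missing_tn": tn_missing,
            "n_spectra": len(spectra),
        }
        report["features"] = [
            {
                "patient_id": f.patient_id,
                "t_b": f.t_b,
                "t_t": f.t_t,
                "t_n": f.t_n,
                "shift_tt_tb": f.shift_tt_tb,
                "shift_tb_tn": f.shift_tb_tn,
            }
            for f in features
        ]

        stage = "group_summaries"
        report["group_summaries"] = _stage_group_summaries(records, features, config)

        stage = "difference_spectrum"
        report["difference_spectrum"] = _stage_difference_spectrum(records, spectra, config)

        stage = "cutoffs"
        cutoffs = _stage_cutoffs(records, features, config)
        report["cutoffs"] = {
            k: {kk: vv for kk, vv in v.items() if not kk.startswith("_")}
            for k, v in cutoffs.items()
        }

        stage = "univariate"
        report["univariate"], report["km_curves"] = _stage_univariate(
            records, features, cutoffs, config
        )

        stage = "cox"
        report["cox"] = _stage_cox(records, features, cutoffs, config)

        stage = "correlations"
        report["correlations"] = _stage_correlations(records, features)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise PipelineError(stage, exc) from exc
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Load the cohort named in the config, analyse it and write the report."""
    if not config.manifest_path or not config.clinical_path:
        raise ValueError("run_pipeline needs manifest_path and clinical_path")
    try:
        _, records, spectra = load_cohort(config.manifest_path, config.clinical_path)
    except Exception as exc:
        raise PipelineError("load", exc) from exc
    report = analyze_cohort(records, spectra, config)
    write_report(report, config.out_dir)
    return report


REPORT_SCHEMA = {
    "required": list(REPORT_SECTIONS),
    "types": {
        "config": dict,
        "cohort": dict,
        "features": list,
        "group_summaries": list,
        "difference_spectrum": dict,
        "cutoffs": dict,
        "univariate": list,
        "km_curves": dict,
        "cox": dict,
        "correlations": dict,
    },
}


def validate_report(report: dict) -> None:
    """Check the report against the shipped section schema; raise on mismatch."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        expected = REPORT_SCHEMA["types"][key]
        if not isinstance(report[key], expected):
            raise ValueError(
                f"report section {key!r} has type {type(report[key]).__name__}, "
                f"expected {expected.__name__}"
            )


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write the report: JSON, CSV tables and KM step tables.

    Content files are deterministic for identical inputs; wall-clock
    metadata is isolated in run_metadata.json.
    """
    validate_report(report)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def dump_json(name: str, payload) -> None:
        p = out / name
        p.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))
        paths[name] = p

    dump_json("report.json", report)
    dump_json("cutoffs.json", report["cutoffs"])
    dump_json("cox.json", report["cox"])

    pd.DataFrame(report["features"]).to_csv(out / "features.csv", index=False)
    pd.DataFrame(report["group_summaries"]).to_csv(
        out / "group_summaries.csv", index=False
    )
    pd.DataFrame(report["univariate"]).to_csv(out / "univariate.csv", index=False)

    diff = report["difference_spectrum"]
    if "wavenumbers" in diff:
        pd.DataFrame(
            {
                "wavenumber_cm-1": diff["wavenumbers"],
                "mean_remission": diff["mean_remission"],
                "mean_relapse": diff["mean_relapse"],
                "difference": diff["difference"],
            }
        ).to_csv(out / "difference_spectrum.csv", index=False)

    for fname, info in report["cutoffs"].items():
        if "roc" in info:
            pd.DataFrame(info["roc"]).to_csv(out / f"roc_{fname}.csv", index=False)

    for key, arms in report["km_curves"].items():
        safe = key.replace("|", "_").replace("/", "-").replace(" ", "")
        for arm, table in arms.items():
            arm_safe = arm.replace("/", "-").replace(" ", "").replace("<", "lt").replace(">=", "ge")
            pd.DataFrame(table).to_csv(out / f"km_{safe}_{arm_safe}.csv", index=False)

    import time

    (out / "run_metadata.json").write_text(
        json.dumps({"written_at_unix": time.time()}, indent=2)
    )
    return paths
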