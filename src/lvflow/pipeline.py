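"""Per-subject analysis and cohort comparison orchestration.

`analyze_subject` runs the full per-subject chain — background phase
correction, regional partition, through-plane flow curves and peaks, kinetic
energy, pathline compartments, and cavity function — and fills the subject
record with the 11 LV flow parameters (peak systolic/diastolic flow in the
base, mid-ventricle and apex; global KEi_EDV; and the four compartment
percentages).  `analyze_cohort` maps it over a cohort directory, skipping
subjects whose inputs fail validation, and writes the demographics,
group-effect and correlation tables plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field as dfield
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as lvio
from .core import FLOW_PARAMETERS, SegmentationCine, SubjectRecord, VelocityField4D
from .cohort_stats import compare_demographics, describe, group_model, spearman_corr
from .flow_metrics import kinetic_energy, partition_regions, peak_flows, throughplane_flow
from .pathlines import trace_compartments
from .preprocessing import correct_background_phase, estimate_static_mask, fit_background_phase
from .ventricular import cavity_volumes, infarct_fraction

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "analyze_subject", "analyze_cohort"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the per-subject analysis."""

    phase_correction: bool = True
    static_percentile: float = 30.0
    pathline_density: float = 0.25
    pathline_substeps: int = 10
    ed_frame: Optional[int] = None  # default: frame of maximum cavity volume
    es_frame: Optional[int] = None  # default: frame of minimum cavity volume
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def analyze_subject(
    field: VelocityField4D,
    seg: SegmentationCine,
    record: SubjectRecord,
    config: AnalysisConfig | None = None,
    pathline_field: Optional[VelocityField4D] = None,
) -> SubjectRecord:
    """Run the full per-subject analysis; fills and returns the record.

    ``pathline_field`` optionally supplies a separate (e.g. low-noise)
    reconstruction for compartment tracking; the primary field is used for
    flow and KE.
    """
    cfg = config or AnalysisConfig()

    if cfg.phase_correction:
        static = estimate_static_mask(field, cfg.static_percentile)
        coeffs = fit_background_phase(field, static)
        field = correct_background_phase(field, coeffs)
        if pathline_field is not None:
            static_p = estimate_static_mask(pathline_field, cfg.static_percentile)
            pathline_field = correct_background_phase(
                pathline_field, fit_background_phase(pathline_field, static_p)
            )

    function = cavity_volumes(seg, heart_rate=record.heart_rate)
    ed = cfg.ed_frame if cfg.ed_frame is not None else function.ed_frame
    es = cfg.es_frame if cfg.es_frame is not None else function.es_frame

    partition = partition_regions(seg, ed_frame=ed)
    curves = throughplane_flow(field, seg, partition)
    peaks = peak_flows(curves)
    ke = kinetic_energy(field, seg, function.edv_ml)
    fractions, _ = trace_compartments(
        pathline_field if pathline_field is not None else field,
        seg,
        partition,
        ed_frame=ed,
        es_frame=es,
        density=cfg.pathline_density,
        substeps=cfg.pathline_substeps,
    )

    record.flow_parameters = {
        "peak_systolic_flow_base": peaks.peak_systolic["base"],
        "peak_systolic_flow_mid": peaks.peak_systolic["mid"],
        "peak_systolic_flow_apex": peaks.peak_systolic["apex"],
        "peak_diastolic_flow_base": peaks.peak_diastolic["base"],
        "peak_diastolic_flow_mid": peaks.peak_diastolic["mid"],
        "peak_diastolic_flow_apex": peaks.peak_diastolic["apex"],
        "kei_edv": ke.kei_edv_uj_ml,
        **fractions.as_dict(),
    }
    record.function = function.as_dict()
    record.function["excluded_pathline_pct"] = fractions.excluded
    if record.infarct_scores is not None:
        record.function["infarct_size_pct"] = infarct_fraction(record.infarct_scores).fraction_pct
    logger.info("subject %s analyzed: %s", record.id, record.flow_parameters)
    return record


def _flow_summary_table(cohort: pd.DataFrame, effects: list) -> pd.DataFrame:
    rows = []
    eff_by_name = {e.parameter: e for e in effects}
    for name in FLOW_PARAMETERS:
        if name not in cohort.columns:
            continue
        ctrl = describe(cohort.loc[cohort["group"] == "control", name])
        ami = describe(cohort.loc[cohort["group"] == "AMI", name])
        row = {
            "parameter": name,
            "control_median": ctrl.center,
            "control_iqr": ctrl.spread,
            "ami_median": ami.center,
            "ami_iqr": ami.spread,
        }
        if name in eff_by_name:
            e = eff_by_name[name]
            row.update(
                {"delta": e.delta, "ci_low": e.ci_low, "ci_high": e.ci_high, "p_value": e.p_value, "n": e.n}
            )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort_dir,
    out_dir,
    config: AnalysisConfig | None = None,
) -> dict:
    """Analyze every subject directory under ``cohort_dir`` and compare groups.

    Subjects whose inputs fail validation are skipped with a logged reason;
    the run aborts only if no subject can be analyzed.  Writes per-subject,
    demographics, group-effect (flow summary) and correlation tables plus a
    manifest with the config hash.  Returns a summary dict.
    """
    cfg = config or AnalysisConfig()
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    subject_dirs = sorted(d for d in cohort_dir.iterdir() if (d / lvio.META_FILENAME).exists())
    if not subject_dirs:
        raise FileNotFoundError(f"no subject datasets found under {cohort_dir}")

    records, failures = [], []
    for sdir in subject_dirs:
        try:
            field, seg, record, pathline_field = lvio.read_subject_dir(sdir)
            if record is None:
                raise ValueError("subject metadata missing from sidecar")
            records.append(
                analyze_subject(field, seg, record, cfg, pathline_field=pathline_field)
            )
        except Exception as exc:  # noqa: BLE001 - a bad subject must not kill the cohort
            logger.warning("skipping subject %s: %s", sdir.name, exc)
            failures.append({"subject": sdir.name, "reason": str(exc)})

    if not records:
        raise RuntimeError("no subject could be analyzed")
    cohort = pd.DataFrame([r.as_row() for r in records])

    tables: dict[str, pd.DataFrame] = {}
    demo_vars = [c for c in ("age", "heart_rate", "sv_ml", "co_l_min", "edv_ml", "ef_pct") if c in cohort.columns]
    groups_present = cohort["group"].nunique() == 2
    effects = []
    if groups_present:
        tables["demographics"] = compare_demographics(cohort, continuous=demo_vars)
        for name in FLOW_PARAMETERS:
            try:
                effects.append(group_model(cohort, name))
            except ValueError as exc:
                logger.warning("group model for %s failed: %s", name, exc)
        # correlations of regional flows with HR and traditional CMR measures
        corr_rows = []
        cmr_vars = [v for v in ("heart_rate", "sv_ml", "co_l_min", "ef_pct", "edv_ml", "infarct_size_pct") if v in cohort.columns]
        flow_vars = [p for p in FLOW_PARAMETERS if "flow" in p and p in cohort.columns]
        for fv in flow_vars:
            for cv in cmr_vars:
                sub = cohort[[fv, cv]].dropna()
                if len(sub) < 3 or np.ptp(sub[fv]) == 0 or np.ptp(sub[cv]) == 0:
                    continue
                res = spearman_corr(sub[fv], sub[cv], names=(fv, cv))
                corr_rows.append(
                    {"flow_parameter": fv, "variable": cv, "rho": res.rho, "p_value": res.p_value, "n": res.n}
                )
        tables["correlations"] = pd.DataFrame(corr_rows)
    else:
        logger.warning("single-group cohort: descriptives only, comparison skipped")
    tables["flow_summary"] = _flow_summary_table(cohort, effects)

    paths = lvio.write_results(records, tables, out_dir)
    manifest = {
        "n_subjects": len(records),
        "n_failed": len(failures),
        "failures": failures,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "tables": {k: str(v) for k, v in paths.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"cohort": cohort, "tables": tables, "manifest": manifest, "paths": paths}
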