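"""Threshold classification of early treatment response and orchestration.

The headline computation: percent change of a metabolic metric between the
pre-treatment scan and the day-7-11 follow-up, a fixed-threshold call
(responder iff LAC/PYR change >= +20%, or kPL change >= -15%), and
cohort-level confusion summaries against the pathological complete
response (pCR) label at surgery.  Patients on PARP-inhibitor treatment are
classified but reported in a separate stratum: PARP inhibition can raise
lactate labeling pharmacodynamically regardless of response, so they never
enter the standard-of-care threshold-validation counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .hp_simulator import CohortConfig, simulate_cohort

__all__ = [
    "ResponseCall",
    "percent_change",
    "classify_lacpyr",
    "classify_kpl",
    "evaluate_cohort",
    "run_pipeline",
    "recompute_cohort_summaries",
    "LACPYR_THRESHOLD",
    "KPL_THRESHOLD",
]

LACPYR_THRESHOLD = 20.0   # percent; responder iff change >= +20 (inclusive)
KPL_THRESHOLD = -15.0     # percent; responder iff change >= -15 (above)


@dataclass(frozen=True)
class ResponseCall:
    """One threshold classification of one metric for one patient."""

    metric_name: str
    pct_change: float
    threshold: float
    predicted_responder: bool
    rule_direction: str = ">="

    def __post_init__(self) -> None:
        if self.predicted_responder != (self.pct_change >= self.threshold):
            raise ValueError("call inconsistent with its threshold rule")


def percent_change(baseline: float, followup: float) -> float:
    """Percent change relative to baseline: 100 (followup - baseline)/baseline."""
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    if not np.isfinite(followup):
        raise ValueError("followup must be finite")
    return 100.0 * (followup - baseline) / baseline


def classify_lacpyr(pct_change: float,
                    threshold: float = LACPYR_THRESHOLD) -> ResponseCall:
    """Responder iff the LAC/PYR change is at least +20% (boundary inclusive)."""
    if not np.isfinite(pct_change):
        raise ValueError("pct_change must be finite")
    return ResponseCall("lacpyr", float(pct_change), threshold,
                        pct_change >= threshold)


def classify_kpl(pct_change: float,
                 threshold: float = KPL_THRESHOLD) -> ResponseCall | None:
    """Responder iff the kPL change is above -15%; ``None`` when kPL is missing.

    A missing kPL (technical failure) withholds the call rather than
    defaulting to either class.
    """
    if pct_change is None or (isinstance(pct_change, float)
                              and math.isnan(pct_change)):
        return None
    if not np.isfinite(pct_change):
        raise ValueError("pct_change must be finite")
    return ResponseCall("kpl", float(pct_change), threshold,
                        pct_change >= threshold)


def evaluate_cohort(records: pd.DataFrame, calls: pd.DataFrame
                    ) -> dict[str, Any]:
    """Confusion summary of calls against pCR labels.

    ``records`` needs columns patient_id, pcr_label, parp_flag; ``calls``
    needs patient_id, metric, predicted_responder.  Counts are reported
    overall and restricted to standard-of-care (non-PARP) patients; PARP
    patients whose call disagrees with their label are listed as the
    separate exception stratum.
    """
    if records["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids in records")
    unmatched = set(calls["patient_id"]) - set(records["patient_id"])
    if unmatched:
        raise ValueError(f"calls reference unknown patients: {sorted(unmatched)}")
    if records["pcr_label"].isna().any():
        raise ValueError("every record needs a pcr_label")

    merged = calls.merge(records[["patient_id", "pcr_label", "parp_flag"]],
                         on="patient_id", how="left")
    out: dict[str, Any] = {}
    for metric, grp in merged.groupby("metric"):
        pred = grp["predicted_responder"].astype(bool)
        truth = grp["pcr_label"].astype(bool)
        parp = grp["parp_flag"].astype(bool)

        def counts(sel: pd.Series) -> dict[str, int]:
            p, y = pred[sel], truth[sel]
            return {"tp": int((p & y).sum()), "fp": int((p & ~y).sum()),
                    "tn": int((~p & ~y).sum()), "fn": int((~p & y).sum()),
                    "n_called": int(sel.sum())}

        exceptions = grp.loc[parp & (pred != truth), "patient_id"].tolist()
        out[metric] = {
            "overall": counts(pd.Series(True, index=grp.index)),
            "standard_of_care": counts(~parp),
            "parp_exceptions": exceptions,
        }
    return out


def _make_calls(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient metric rows and threshold calls from a cohort table."""
    metric_rows, call_rows = [], []
    for _, row in cohort.iterrows():
        pid = row["patient_id"]
        status = "complete"
        try:
            d_lp = percent_change(row["baseline_lacpyr"], row["followup_lacpyr"])
        except (ValueError, TypeError):
            d_lp = math.nan
            status = "incomplete"
        if math.isnan(float(row.get("followup_lacpyr", math.nan))):
            d_lp, status = math.nan, "incomplete"

        kpl_b, kpl_f = row.get("baseline_kpl"), row.get("followup_kpl")
        if kpl_b is None or kpl_f is None or math.isnan(float(kpl_b)) \
                or math.isnan(float(kpl_f)):
            d_kpl = math.nan
        else:
            d_kpl = percent_change(float(kpl_b), float(kpl_f))

        metric_rows.append({"patient_id": pid, "status": status,
                            "lacpyr_pct_change": d_lp,
                            "kpl_pct_change": d_kpl})
        if status == "complete":
            call = classify_lacpyr(d_lp)
            call_rows.append({"patient_id": pid, "metric": "lacpyr",
                              "pct_change": call.pct_change,
                              "threshold": call.threshold,
                              "predicted_responder": call.predicted_responder})
        kcall = classify_kpl(d_kpl)
        if kcall is not None:
            call_rows.append({"patient_id": pid, "metric": "kpl",
                              "pct_change": kcall.pct_change,
                              "threshold": kcall.threshold,
                              "predicted_responder": kcall.predicted_responder})
    return pd.DataFrame(metric_rows), pd.DataFrame(call_rows)


def run_pipeline(config: dict[str, Any] | None = None,
                 out_dir: str | Path | None = None) -> dict[str, Any]:
    """End-to-end synthetic-cohort run: simulate, measure, classify, report.

    ``config`` keys (all optional): ``seed``, ``n_patients``,
    ``n_responders``, ``cohort_csv`` (use an existing per-patient table
    instead of simulating one).  Outputs ``metrics.csv``, ``calls.csv`` and
    ``report.md`` when ``out_dir`` is given.  Deterministic given config
    and seed; patients with missing follow-up are carried through with
    status "incomplete", never dropped.
    """
    cfg = dict(config or {})
    known = {"seed", "n_patients", "n_responders", "cohort_csv"}
    bad = set(cfg) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")

    if "cohort_csv" in cfg:
        cohort = pd.read_csv(cfg["cohort_csv"])
        required = {"patient_id", "pcr_label", "parp_flag",
                    "baseline_lacpyr", "followup_lacpyr"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    else:
        cohort = simulate_cohort(CohortConfig(
            seed=int(cfg.get("seed", 0)),
            n_patients=int(cfg.get("n_patients", 7)),
            n_responders=int(cfg.get("n_responders", 3))))

    metrics, calls = _make_calls(cohort)
    summary = evaluate_cohort(cohort, calls) if len(calls) else {}

    result = {"cohort": cohort, "metrics": metrics, "calls": calls,
              "summary": summary, "config": cfg}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.merge(metrics, on="patient_id").to_csv(
            out / "metrics.csv", index=False, float_format="%.6g")
        calls.to_csv(out / "calls.csv", index=False, float_format="%.6g")
        (out / "report.md").write_text(_render_report(result))
    return result


def _render_report(result: dict[str, Any]) -> str:
    lines = ["# Response-assessment report", "",
             f"Config: {result['config']}", "",
             f"Patients: {len(result['cohort'])} "
             f"({int(result['cohort']['pcr_label'].sum())} pCR, "
             f"{int(result['cohort']['parp_flag'].sum())} on PARP inhibitor)",
             "",
             f"Thresholds: LAC/PYR >= +{LACPYR_THRESHOLD:g}% (inclusive), "
             f"kPL >= {KPL_THRESHOLD:g}%", ""]
    for metric, s in result["summary"].items():
        soc, ov = s["standard_of_care"], s["overall"]
        lines += [f"## {metric}",
                  f"- overall: TP={ov['tp']} FP={ov['fp']} TN={ov['tn']} "
                  f"FN={ov['fn']} (n={ov['n_called']})",
                  f"- standard of care: TP={soc['tp']} FP={soc['fp']} "
                  f"TN={soc['tn']} FN={soc['fn']} (n={soc['n_called']})",
                  f"- PARP exceptions: {s['parp_exceptions'] or 'none'}", ""]
    incomplete = result["metrics"].query("status == 'incomplete'")
    if len(incomplete):
        lines += ["## Incomplete patients",
                  ", ".join(incomplete["patient_id"]), ""]
    return "\n".join(lines)


def recompute_cohort_summaries(table: pd.DataFrame) -> dict[str, Any]:
    """Recompute study-style cohort summaries from a per-patient metric table.

    Given a table with the per-patient baseline/follow-up metric columns
    (the layout of a supplementary per-patient results table), returns the
    baseline cohort means, the pairwise Pearson correlations between the
    13C metrics and volume, and the +20% LAC/PYR rule's prediction counts.
    """
    from .cohort_stats_survival import pearson_test

    means = {c: float(table[c].mean())
             for c in ("baseline_lacpyr", "baseline_kpl", "baseline_snr_pyr",
                       "baseline_snr_lac") if c in table}
    correlations = {}
    pairs = [("baseline_snr_pyr", "baseline_volume_ml"),
             ("baseline_snr_lac", "baseline_volume_ml"),
             ("baseline_lacpyr", "baseline_volume_ml"),
             ("baseline_kpl", "baseline_f")]
    for a, b in pairs:
        if a in table and b in table:
            sub = table[[a, b]].dropna()
            if len(sub) >= 3:
                res = pearson_test(sub[a].to_numpy(), sub[b].to_numpy())
                correlations[f"{a}_vs_{b}"] = {"r": res.statistic,
                                               "p": res.p_value, "n": res.n}
    _, calls = _make_calls(table)
    summary = evaluate_cohort(table, calls)
    return {"baseline_means": means, "correlations": correlations,
            "classification": summary}
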