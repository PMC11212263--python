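"""Paired statistical comparison of templates over atlas regions.

For each held-out validation subject and each of two templates, the subject
is registered to the template, displacement and |log J| maps are computed in
template space and transported to one common reference grid, and per-region
means are taken.  The per-subject region means are the paired observations:
for every retained region a paired t-test compares template A against
template B, with Bonferroni control at alpha divided by the number of
regions actually retained after the small-region volume filter (per metric
family).  A region is flagged directional only when it is significant AND
its means differ strictly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import LabelAtlas, ValidationError
from .deformation_metrics import (abs_log_jacobian, displacement_map, jacobian_map,
                                  region_summary, to_common_space)
from .registration import RegistrationParams, register
from .template_builder import Template

log = logging.getLogger(__name__)


def paired_t(x, y):
    """Two-sided paired t-test; returns (t, p, df).

    t = mean(x - y) / (sd(x - y) / sqrt(n)) with df = n - 1.  All-zero
    differences give (0, 1); zero variance with nonzero mean gives p = 0
    with a degenerate-variance warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("paired_t requires equal-length samples")
    n = x.size
    if n < 2:
        raise ValidationError("paired_t needs at least 2 pairs")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0):
            return 0.0, 1.0, df
        log.warning("paired_t: zero variance with nonzero mean difference")
        return float(np.sign(d.mean()) * np.inf), 0.0, df
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"number of tests must be >= 1, got {m}")
    return alpha / m


@dataclass
class ComparisonReport:
    """Region-wise paired comparison of two templates for one metric.

    ``table`` rows: region_id, name, mean_A, sd_A, mean_B, sd_B, t_statistic,
    p_value, significant, direction ('A<B', 'B<A', 'none').  ``summary``:
    n_regions_tested, n_significant_A_less, n_significant_B_less, alpha,
    threshold, metric.
    """

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        if len(t):
            if ((t["p_value"] < 0) | (t["p_value"] > 1)).any():
                raise ValidationError("p-values outside [0, 1]")
            thr = self.summary["threshold"]
            if not (t["significant"] == (t["p_value"] < thr)).all():
                raise ValidationError("significance flags inconsistent with threshold")
        for direction, key in (("A<B", "n_significant_A_less"), ("B<A", "n_significant_B_less")):
            n = int((t["direction"] == direction).sum()) if len(t) else 0
            if self.summary.get(key, n) != n:
                raise ValidationError(f"summary count {key} inconsistent with table")


def _metric_report(per_subject: pd.DataFrame, value_col: str, alpha: float,
                   metric_name: str) -> ComparisonReport:
    """Build one report from long-format per-subject region means (A and B columns)."""
    regions = per_subject[["region_id", "name"]].drop_duplicates().sort_values("region_id")
    m = len(regions)
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for _, reg in regions.iterrows():
        sub = per_subject[per_subject["region_id"] == reg["region_id"]].sort_values("subject_id")
        a = sub[f"{value_col}_A"].to_numpy()
        b = sub[f"{value_col}_B"].to_numpy()
        t, p, df = paired_t(a, b)
        sig = bool(p < threshold)
        if sig and a.mean() < b.mean():
            direction = "A<B"
        elif sig and b.mean() < a.mean():
            direction = "B<A"
        else:
            direction = "none"
        rows.append({"region_id": int(reg["region_id"]), "name": reg["name"],
                     "mean_A": a.mean(), "sd_A": a.std(ddof=1),
                     "mean_B": b.mean(), "sd_B": b.std(ddof=1),
                     "t_statistic": t, "p_value": p, "df": df,
                     "significant": sig, "direction": direction})
    table = pd.DataFrame(rows)
    summary = {"metric": metric_name, "n_regions_tested": m, "alpha": alpha,
               "threshold": threshold,
               "n_significant_A_less": int((table["direction"] == "A<B").sum()),
               "n_significant_B_less": int((table["direction"] == "B<A").sum())}
    return ComparisonReport(table=table, summary=summary)


def subject_template_region_means(subject, template: Template, atlas: LabelAtlas,
                                  common_reference: Template, bridge,
                                  params: RegistrationParams = None,
                                  min_volume_mm3: float = 500.0) -> pd.DataFrame:
    """Register one subject to one template; region means in the common space.

    `bridge` is the deformation carrying maps from the template's space to
    the common-reference grid (None for the reference itself).
    """
    channels = subject.channels if hasattr(subject, "channels") else list(subject)
    vel, d = register(list(channels), list(template.channels), params)
    disp = displacement_map(d)
    logj = jacobian_map(d, log_output=True)
    alj = abs_log_jacobian(logj)
    if bridge is not None:
        disp = to_common_space(disp, bridge)
        alj = to_common_space(alj, bridge)
    return region_summary(disp, alj, atlas, min_volume_mm3)


def compare_templates(validation_subjects, template_A: Template, template_B: Template,
                      atlas: LabelAtlas, common_reference: Template = None,
                      alpha: float = 0.05, min_volume_mm3: float = 500.0,
                      params: RegistrationParams = None,
                      bridge_params: RegistrationParams = None):
    """Full template-comparison experiment; returns (displacement report, |log J| report).

    Validation subjects must be disjoint from both templates' construction
    sets (checked via subject ids).  The common reference defaults to
    template A; each template's T1 channel is registered to the reference's
    T1 to obtain the bridge that transports metric maps into the common
    frame before any averaging across subjects.
    """
    if not validation_subjects:
        raise ValidationError("validation subject list is empty")
    val_ids = [getattr(s, "subject_id", f"val{i:03d}") for i, s in enumerate(validation_subjects)]
    construction = set(template_A.subject_ids) | set(template_B.subject_ids)
    overlap = sorted(set(val_ids) & construction)
    if overlap:
        raise ValidationError(
            f"validation subjects overlap template construction sets: {overlap}")
    if common_reference is None:
        common_reference = template_A
    bridge_params = bridge_params or params

    bridges = {}
    for key, tpl in (("A", template_A), ("B", template_B)):
        if tpl is common_reference:
            bridges[key] = None
        else:
            _, bridges[key] = register([tpl.t1], [common_reference.t1], bridge_params)

    same_object = template_A is template_B
    records = []
    for sid, subj in zip(val_ids, validation_subjects):
        means = {}
        means["A"] = subject_template_region_means(
            subj, template_A, atlas, common_reference, bridges["A"], params, min_volume_mm3)
        means["B"] = (means["A"] if same_object else subject_template_region_means(
            subj, template_B, atlas, common_reference, bridges["B"], params, min_volume_mm3))
        merged = means["A"].merge(means["B"], on=["region_id", "name"], suffixes=("_A", "_B"))
        merged["subject_id"] = sid
        records.append(merged)
    per_subject = pd.concat(records, ignore_index=True)

    rep_disp = _metric_report(per_subject, "mean_displacement_mm", alpha, "displacement_mm")
    rep_alj = _metric_report(per_subject, "mean_abs_log_jacobian", alpha, "abs_log_jacobian")
    return rep_disp, rep_alj


def swap_report(report: ComparisonReport) -> ComparisonReport:
    """The report with templates A and B exchanged (mirror of direction flags)."""
    t = report.table.copy()
    t[["mean_A", "mean_B"]] = t[["mean_B", "mean_A"]].to_numpy()
    t[["sd_A", "sd_B"]] = t[["sd_B", "sd_A"]].to_numpy()
    t["t_statistic"] = -t["t_statistic"]
    t["direction"] = t["direction"].map({"A<B": "B<A", "B<A": "A<B", "none": "none"})
    s = dict(report.summary)
    s["n_significant_A_less"], s["n_significant_B_less"] = (
        s["n_significant_B_less"], s["n_significant_A_less"])
    return ComparisonReport(table=t, summary=s)


def report_text_block(report: ComparisonReport, label_A: str = "A", label_B: str = "B") -> str:
    """Human-readable summary mirroring a region / mean+-sd / t / p table layout."""
    lines = [f"# metric: {report.summary['metric']}  "
             f"(alpha={report.summary['alpha']}, threshold={report.summary['threshold']:.3e}, "
             f"m={report.summary['n_regions_tested']})",
             f"{'region':<24}{label_A + ' mean±sd':>20}{label_B + ' mean±sd':>20}"
             f"{'t':>10}{'p':>12}  direction"]
    for _, r in report.table.iterrows():
        lines.append(f"{r['name']:<24}{r['mean_A']:>10.3f}±{r['sd_A']:<8.3f}"
                     f"{r['mean_B']:>10.3f}±{r['sd_B']:<8.3f}"
                     f"{r['t_statistic']:>10.2f}{r['p_value']:>12.2e}  {r['direction']}")
    lines.append(f"significant {label_A}<{label_B}: {report.summary['n_significant_A_less']}, "
                 f"{label_B}<{label_A}: {report.summary['n_significant_B_less']} "
                 f"of {report.summary['n_regions_tested']} regions")
    return "\n".join(lines)
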