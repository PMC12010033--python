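"""End-to-end validation analysis of the risk score on a cohort.

Reproduces the study's analysis plan on any validated cohort:

1. score every patient (four components + total);
2. compare the total score across the two levels of each one-year outcome
   (vital status, postoperative comorbidity, prosthesis use, wound
   complications) with median, quartiles and a Mann–Whitney test;
3. ROC of the score against one-year mortality, in an explicit, caller-
   chosen orientation — both AUC and 1−AUC are always reported because the
   discriminative direction of a small-cohort score can be ambiguous;
4. Spearman correlation of the score with the 3-month Katz ADL score,
   excluding patients who died within the first three months (< 90 days);
5. mean-score decomposition by age band.

Quartiles use linear interpolation between order statistics (small-n
quartiles are convention-sensitive; the convention is stated in the report
footer).  No multiple-testing adjustment is applied, and the report says so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import AnalysisError
from .scoring import AgeBand, Mobilization, age_band, total_score
from .stats import (
    MannWhitneyResult,
    RocResult,
    SpearmanResult,
    mann_whitney,
    roc_auc,
)
from . import stats as _stats

__all__ = [
    "OUTCOME_FIELDS",
    "EARLY_DEATH_CUTOFF_DAYS",
    "GroupStats",
    "GroupComparisonResult",
    "KatzCorrelationResult",
    "AgeBandSummary",
    "AnalysisReport",
    "score_cohort",
    "compare_groups",
    "mortality_roc",
    "katz_correlation",
    "age_band_summaries",
    "run_full_analysis",
    "report_text",
    "report_json",
]

EARLY_DEATH_CUTOFF_DAYS = 90  # "first three months" exclusion for Katz
# outcome column -> (name, label when False, label when True)
OUTCOME_FIELDS = {
    "died_within_1yr": ("One-year survival status", "Survived", "Deceased"),
    "postop_comorbidity": ("Postoperative comorbidity", "Absent", "Present"),
    "prosthetic_usage": ("Prosthetic usage", "Absent", "Present"),
    "wound_complication": ("Postoperative wound complications", "Absent", "Present"),
}
# exact Mann-Whitney p is used whenever the pooled size permits it
_EXACT_LIMIT = _stats.EXACT_POOLED_LIMIT


def score_cohort(cohort: CohortTable) -> pd.DataFrame:
    """One row per patient: input fields plus the five score columns."""
    rows = []
    for rec in cohort:
        br = total_score(rec)
        katz = rec.katz
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age_years": rec.age_years,
                "age_band": age_band(rec.age_years).value,
                "mobilization": rec.mobilization.value,
                "died_within_1yr": rec.died_within_1yr,
                "days_to_death": rec.days_to_death,
                "postop_comorbidity": rec.postop_comorbidity,
                "prosthetic_usage": rec.prosthetic_usage,
                "wound_complication": rec.wound_complication,
                "age_points": br.age_points,
                "comorbidity_points": br.comorbidity_points,
                "mobilization_points": br.mobilization_points,
                "complication_points": br.complication_points,
                "total_score": br.total,
                "katz_score": katz.score if katz is not None else None,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    median: float
    p25: float
    p75: float


@dataclass(frozen=True)
class GroupComparisonResult:
    """One outcome row: per-group descriptives plus the rank test."""

    outcome_name: str
    groups: tuple  # (GroupStats, GroupStats); first group = outcome absent
    u_statistic: float
    z_statistic: float
    p_value: float
    method: str

    @property
    def mann_whitney(self) -> MannWhitneyResult:
        return MannWhitneyResult(
            self.u_statistic,
            self.z_statistic,
            self.p_value,
            self.method,
            self.groups[0].n,
            self.groups[1].n,
        )


def _quartiles(values: np.ndarray) -> tuple:
    p25, med, p75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(p25), float(med), float(p75)


def compare_groups(cohort: CohortTable, outcome_field: str) -> GroupComparisonResult:
    """Compare total scores between the two levels of a binary outcome.

    The first group is the outcome-absent level (survived / absent).  The
    Mann–Whitney p is exact whenever the pooled size allows it.
    """
    if outcome_field not in OUTCOME_FIELDS:
        raise AnalysisError(
            f"unknown outcome field {outcome_field!r}; "
            f"expected one of {sorted(OUTCOME_FIELDS)}"
        )
    name, label_false, label_true = OUTCOME_FIELDS[outcome_field]
    scores = {False: [], True: []}
    for rec in cohort:
        scores[bool(getattr(rec, outcome_field))].append(total_score(rec).total)
    if not scores[False] or not scores[True]:
        raise AnalysisError(
            f"{name}: both outcome levels must be present to compare"
        )
    a = np.asarray(scores[False], dtype=float)
    b = np.asarray(scores[True], dtype=float)
    method = "exact" if len(a) + len(b) <= _EXACT_LIMIT else "auto"
    mw = mann_whitney(a, b, method=method)
    ga = GroupStats(label_false, len(a), *_reorder(_quartiles(a)))
    gb = GroupStats(label_true, len(b), *_reorder(_quartiles(b)))
    return GroupComparisonResult(
        outcome_name=name,
        groups=(ga, gb),
        u_statistic=mw.u_statistic,
        z_statistic=mw.z_statistic,
        p_value=mw.p_value,
        method=mw.method,
    )


def _reorder(q: tuple) -> tuple:
    p25, med, p75 = q
    return med, p25, p75


def mortality_roc(
    cohort: CohortTable, direction: str = "higher_score_positive"
) -> RocResult:
    """ROC of the total score against one-year mortality."""
    scores, died = [], []
    for rec in cohort:
        scores.append(total_score(rec).total)
        died.append(rec.died_within_1yr)
    if len(set(died)) < 2:
        raise AnalysisError(
            "mortality ROC requires both survivors and deceased patients"
        )
    return roc_auc(scores, died, positive_label="died_within_1yr",
                   direction=direction)


@dataclass(frozen=True)
class KatzCorrelationResult:
    """Score–Katz correlation among patients alive at the 3-month mark."""

    spearman: SpearmanResult
    analyzable_n: int
    excluded_early_death_n: int
    missing_katz_n: int  # alive at 3 months but never assessed


def _katz_partition(cohort: CohortTable):
    analyzable, excluded, missing = [], 0, 0
    for rec in cohort:
        if rec.died_within_1yr and rec.days_to_death < EARLY_DEATH_CUTOFF_DAYS:
            excluded += 1
        elif rec.katz_components is None:
            missing += 1
        else:
            analyzable.append(rec)
    return analyzable, excluded, missing


def katz_correlation(cohort: CohortTable) -> KatzCorrelationResult:
    """Spearman correlation of risk score vs 3-month Katz score.

    Patients who died before day 90 were never assessed and are excluded;
    3-month survivors without Katz data are counted separately, not imputed.
    """
    analyzable, excluded, missing = _katz_partition(cohort)
    if len(analyzable) < 3:
        raise AnalysisError(
            f"Katz correlation needs >= 3 analyzable records, "
            f"got {len(analyzable)}"
        )
    x = [total_score(r).total for r in analyzable]
    y = [r.katz.score for r in analyzable]
    sp = _stats.spearman(x, y)
    return KatzCorrelationResult(
        spearman=sp,
        analyzable_n=len(analyzable),
        excluded_early_death_n=excluded,
        missing_katz_n=missing,
    )


@dataclass(frozen=True)
class AgeBandSummary:
    """Mean-score decomposition within one age band.

    The four component means sum to the mean total exactly; means are None
    for an empty band.
    """

    band: AgeBand
    n: int
    mean_total_score: float | None
    mean_age_points: float | None
    mean_comorbidity_points: float | None
    mean_mobilization_points: float | None
    mean_complication_points: float | None
    early_mobilization_fraction: float | None
    mortality_fraction: float | None
    mean_katz: float | None  # among analyzable 3-month survivors


def age_band_summaries(cohort: CohortTable) -> tuple:
    """One summary per age band (empty bands reported with n=0)."""
    if len(cohort) == 0:
        raise AnalysisError("cannot summarize an empty cohort")
    by_band = {band: [] for band in AgeBand}
    for rec in cohort:
        by_band[age_band(rec.age_years)].append(rec)
    out = []
    for band in AgeBand:
        recs = by_band[band]
        if not recs:
            out.append(AgeBandSummary(band, 0, *([None] * 8)))
            continue
        brs = [total_score(r) for r in recs]
        analyzable, _, _ = _katz_partition(CohortTable(tuple(recs)))
        katz_scores = [r.katz.score for r in analyzable]
        out.append(
            AgeBandSummary(
                band=band,
                n=len(recs),
                mean_total_score=float(np.mean([b.total for b in brs])),
                mean_age_points=float(np.mean([b.age_points for b in brs])),
                mean_comorbidity_points=float(
                    np.mean([b.comorbidity_points for b in brs])
                ),
                mean_mobilization_points=float(
                    np.mean([b.mobilization_points for b in brs])
                ),
                mean_complication_points=float(
                    np.mean([b.complication_points for b in brs])
                ),
                early_mobilization_fraction=float(
                    np.mean([r.mobilization is Mobilization.EARLY for r in recs])
                ),
                mortality_fraction=float(
                    np.mean([r.died_within_1yr for r in recs])
                ),
                mean_katz=(
                    float(np.mean(katz_scores)) if katz_scores else None
                ),
            )
        )
    return tuple(out)


@dataclass(frozen=True)
class AnalysisReport:
    """Everything the full analysis computes on one cohort."""

    n: int
    mean_age: float
    mean_score: float
    mortality_fraction: float
    scored: pd.DataFrame
    comparisons: dict  # outcome field -> GroupComparisonResult | str
    roc: RocResult | str
    katz: KatzCorrelationResult | str
    band_summaries: tuple
    katz_excluded_n: int


def run_full_analysis(
    cohort: CohortTable, direction: str = "higher_score_positive"
) -> AnalysisReport:
    """Score a cohort and run every validation analysis on it.

    Sections that cannot be computed on the given cohort (an outcome with a
    single level, too little Katz data) are reported as a "not computable"
    note instead of failing the whole report.
    """
    if len(cohort) == 0:
        raise AnalysisError("cannot analyze an empty cohort")
    scored = score_cohort(cohort)

    comparisons = {}
    for outcome in OUTCOME_FIELDS:
        try:
            comparisons[outcome] = compare_groups(cohort, outcome)
        except AnalysisError as exc:
            comparisons[outcome] = f"not computable: {exc}"
    try:
        roc = mortality_roc(cohort, direction=direction)
    except AnalysisError as exc:
        roc = f"not computable: {exc}"
    try:
        katz = katz_correlation(cohort)
    except AnalysisError as exc:
        katz = f"not computable: {exc}"

    _, excluded, _ = _katz_partition(cohort)
    return AnalysisReport(
        n=len(cohort),
        mean_age=float(scored["age_years"].mean()),
        mean_score=float(scored["total_score"].mean()),
        mortality_fraction=float(scored["died_within_1yr"].mean()),
        scored=scored,
        comparisons=comparisons,
        roc=roc,
        katz=katz,
        band_summaries=age_band_summaries(cohort),
        katz_excluded_n=excluded,
    )


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _fmt(x, nd: int = 2) -> str:
    return "-" if x is None else f"{x:.{nd}f}"


def report_text(report: AnalysisReport) -> str:
    """Human-readable report: outcome table, ROC, Katz correlation, bands."""
    lines = []
    w = lines.append
    w("Risk-score validation report")
    w("=" * 60)
    w(f"Patients: {report.n}")
    w(f"Mean age: {report.mean_age:.1f} years")
    w(f"Mean total score: {report.mean_score:.2f} (range 0-12)")
    w(f"One-year mortality: {report.mortality_fraction:.1%}")
    w("")
    w("Score by one-year outcome (Mann-Whitney)")
    w("-" * 60)
    header = (
        f"{'Outcome':<34}{'Group':<10}{'n':>3}{'Median':>8}"
        f"{'P25-P75':>12}{'U':>7}{'z':>8}{'p':>8}"
    )
    w(header)
    for outcome, comp in report.comparisons.items():
        if isinstance(comp, str):
            w(f"{OUTCOME_FIELDS[outcome][0]:<34}{comp}")
            continue
        g0, g1 = comp.groups
        w(
            f"{comp.outcome_name:<34}{g0.label:<10}{g0.n:>3}{g0.median:>8.1f}"
            f"{_fmt(g0.p25,1)+'-'+_fmt(g0.p75,1):>12}"
            f"{comp.u_statistic:>7.1f}{comp.z_statistic:>8.2f}"
            f"{_fmt_p(comp.p_value):>8}"
        )
        w(
            f"{'':<34}{g1.label:<10}{g1.n:>3}{g1.median:>8.1f}"
            f"{_fmt(g1.p25,1)+'-'+_fmt(g1.p75,1):>12}"
        )
    w("")
    w("ROC: total score vs one-year mortality")
    w("-" * 60)
    if isinstance(report.roc, str):
        w(report.roc)
    else:
        w(f"Orientation: {report.roc.direction}")
        w(f"AUC = {report.roc.auc:.3f}")
        w(f"AUC under the opposite orientation = {report.roc.auc_complement:.3f}")
    w("")
    w("Spearman: total score vs 3-month Katz ADL score")
    w("-" * 60)
    if isinstance(report.katz, str):
        w(report.katz)
    else:
        sp = report.katz.spearman
        w(
            f"r = {sp.r:.3f} (p = {_fmt_p(sp.p_value)}, n = {sp.n}, "
            f"band = {sp.band.value})"
        )
        w(
            f"Excluded (death before day {EARLY_DEATH_CUTOFF_DAYS}): "
            f"{report.katz.excluded_early_death_n}; "
            f"alive without Katz data: {report.katz.missing_katz_n}"
        )
    w("")
    w("Mean-score decomposition by age band")
    w("-" * 60)
    w(
        f"{'Band':<10}{'n':>3}{'Score':>7}{'Age':>6}{'Comorb':>8}"
        f"{'Mobil':>7}{'Compl':>7}{'Early%':>8}{'Died%':>7}{'Katz':>6}"
    )
    for s in report.band_summaries:
        w(
            f"{s.band.value:<10}{s.n:>3}{_fmt(s.mean_total_score):>7}"
            f"{_fmt(s.mean_age_points):>6}{_fmt(s.mean_comorbidity_points):>8}"
            f"{_fmt(s.mean_mobilization_points):>7}"
            f"{_fmt(s.mean_complication_points):>7}"
            f"{_fmt(None if s.early_mobilization_fraction is None else 100 * s.early_mobilization_fraction, 0):>8}"
            f"{_fmt(None if s.mortality_fraction is None else 100 * s.mortality_fraction, 0):>7}"
            f"{_fmt(s.mean_katz):>6}"
        )
    w("")
    w("Notes: quartiles use linear interpolation between order statistics;")
    w("p-values are two-sided and unadjusted for multiple testing (none is")
    w("applied); the signed z corresponds to the deviate some published")
    w("tables print in their 'U' column.")
    return "\n".join(lines) + "\n"


def report_json(report: AnalysisReport) -> str:
    """Machine-readable JSON mirror of the report (stable key order)."""

    def comp_dict(comp):
        if isinstance(comp, str):
            return {"status": comp}
        return {
            "outcome": comp.outcome_name,
            "groups": [
                {
                    "label": g.label,
                    "n": g.n,
                    "median": g.median,
                    "p25": g.p25,
                    "p75": g.p75,
                }
                for g in comp.groups
            ],
            "u_statistic": comp.u_statistic,
            "z_statistic": comp.z_statistic,
            "p_value": comp.p_value,
            "method": comp.method,
        }

    data = {
        "n": report.n,
        "mean_age": report.mean_age,
        "mean_score": report.mean_score,
        "mortality_fraction": report.mortality_fraction,
        "comparisons": {k: comp_dict(v) for k, v in report.comparisons.items()},
        "roc": (
            {"status": report.roc}
            if isinstance(report.roc, str)
            else {
                "direction": report.roc.direction,
                "auc": report.roc.auc,
                "auc_opposite_orientation": report.roc.auc_complement,
                "points": [list(p) for p in report.roc.points],
            }
        ),
        "katz_correlation": (
            {"status": report.katz}
            if isinstance(report.katz, str)
            else {
                "r": report.katz.spearman.r,
                "p_value": report.katz.spearman.p_value,
                "n": report.katz.spearman.n,
                "band": report.katz.spearman.band.value,
                "excluded_early_death_n": report.katz.excluded_early_death_n,
                "missing_katz_n": report.katz.missing_katz_n,
            }
        ),
        "age_bands": [
            {
                "band": s.band.value,
                "n": s.n,
                "mean_total_score": s.mean_total_score,
                "mean_age_points": s.mean_age_points,
                "mean_comorbidity_points": s.mean_comorbidity_points,
                "mean_mobilization_points": s.mean_mobilization_points,
                "mean_complication_points": s.mean_complication_points,
                "early_mobilization_fraction": s.early_mobilization_fraction,
                "mortality_fraction": s.mortality_fraction,
                "mean_katz": s.mean_katz,
            }
            for s in report.band_summaries
        ],
        "katz_excluded_n": report.katz_excluded_n,
    }
    return json.dumps(data, indent=2, sort_keys=False) + "\n"
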