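"""Platform quality-control metrics for nanowell qPCR panels.

Implements the standard analytical battery used to benchmark miRNA
measurement platforms: detection calls under a Cq cutoff, standard-curve
PCR efficiency, replicate concordance (double/single positives, expression
range, ALC), titration response and its AUC, assay cross-reactivity,
no-template-control positivity, and spike-in dynamic range — all as pure
functions over Cq tables.

Conventions
-----------
* Detection: a cluster is detected when at least ``detection_min_wells`` of
  its wells amplify with Cq strictly below ``cq_cutoff`` (default 34); the
  collapsed Cq is the median (configurable) of those amplified wells.
* Expression is on a log2-like scale where lower Cq means more template:
  ``expression = -ΔCq`` after normalization, or ``-Cq`` raw.
* ALC (area left of the cumulative distribution curve of absolute replicate
  differences) equals the mean absolute difference exactly for a step ECDF;
  lower ALC means better reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .chipio import ChipLayout, Config, CqTable
from .errors import (
    ChipDataError,
    ConsistencyError,
    FitError,
    PartialReportError,
    UndefinedMetricError,
)


@dataclass(frozen=True)
class DetectionCall:
    assay_id: str
    detected: bool
    collapsed_cq: float  # NaN when not detected
    n_wells_amplified: int


@dataclass(frozen=True)
class EfficiencyFit:
    slope: float          # cycles per log10(dilution)
    intercept: float      # cycles
    efficiency_pct: float  # (10**(-1/slope) - 1) * 100
    r_squared: float


@dataclass
class MiRQCReport:
    """The summary table of platform performance parameters."""

    n_clusters_after_cutoff: int
    pct_double_positive: float
    pct_single_positive: float
    expression_range_log2: float
    alc: float
    titration_auc: float
    pct_offtarget_crossreactive: float
    median_relative_crossreactivity: float
    ntc_positive_count: int
    plasma_detected_count: int

    FIELDS = (
        "n_clusters_after_cutoff",
        "pct_double_positive",
        "pct_single_positive",
        "expression_range_log2",
        "alc",
        "titration_auc",
        "pct_offtarget_crossreactive",
        "median_relative_crossreactivity",
        "ntc_positive_count",
        "plasma_detected_count",
    )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def to_csv(self, path) -> None:
        rows = [{"name": k, "value": v} for k, v in asdict(self).items()]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Detection

def call_detection(
    cq_table: CqTable,
    layout: ChipLayout,
    config: Config,
    apply_cq_cutoff: bool = True,
    roles: tuple[str, ...] | None = None,
) -> list[DetectionCall]:
    """Per-cluster detection calls under the Cq cutoff.

    A well counts as amplified when it has a Cq (no-amplification wells
    never count) strictly below ``config.cq_cutoff``; with
    ``apply_cq_cutoff=False`` any amplification signal counts (used for
    no-template controls, where contamination is characteristically late).
    """
    grouped = {
        assay: grp.to_numpy(dtype=float)
        for assay, grp in cq_table.data.groupby("assay_id", sort=False)["cq"]
    }
    calls = []
    for cl in layout.clusters:
        if roles is not None and cl.role not in roles:
            continue
        cqs = grouped.get(cl.assay_id, np.empty(0))
        if cqs.size == 0:
            raise ConsistencyError(
                f"cluster {cl.assay_id!r} absent from table {cq_table.sample_id!r}"
            )
        amplified = np.isfinite(cqs)
        if apply_cq_cutoff:
            amplified &= cqs < config.cq_cutoff
        n_amp = int(amplified.sum())
        detected = n_amp >= config.detection_min_wells
        if detected:
            vals = cqs[amplified]
            collapsed = float(np.median(vals) if config.well_collapse == "median"
                              else np.mean(vals))
        else:
            collapsed = float("nan")
        calls.append(DetectionCall(cl.assay_id, detected, collapsed, n_amp))
    return calls


def calls_by_assay(calls: list[DetectionCall]) -> dict[str, DetectionCall]:
    return {c.assay_id: c for c in calls}


# ---------------------------------------------------------------------------
# Efficiency

def fit_efficiency(series) -> EfficiencyFit:
    """Standard-curve PCR efficiency from a dilution series.

    ``series`` is a sequence of ``(log10_relative_concentration,
    collapsed_cq)`` pairs. Ordinary least squares of Cq on log10
    concentration; efficiency percent is ``(10**(-1/slope) - 1) * 100``
    (the textbook slope -3.32 gives 100%).
    """
    pts = [(float(x), float(y)) for x, y in series]
    if len(pts) < 3:
        raise FitError("efficiency fit needs at least 3 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise FitError("zero spread in concentrations")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise FitError(f"non-negative standard-curve slope {res.slope:.3f}")
    eff = (10.0 ** (-1.0 / res.slope) - 1.0) * 100.0
    return EfficiencyFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency_pct=float(eff),
        r_squared=float(res.rvalue**2),
    )


# ---------------------------------------------------------------------------
# Reproducibility

def replicate_concordance(
    calls_rep1: list[DetectionCall],
    calls_rep2: list[DetectionCall],
) -> tuple[float, float, pd.DataFrame, float]:
    """Double/single-positive percentages and expression correlation.

    Denominator: assays detected in at least one replicate. Returns
    ``(pct_double, pct_single, pairs, pearson_r)`` where ``pairs`` holds the
    double positives' expression values (``-Cq`` here; callers working on
    normalized profiles pass calls whose collapsed values are ΔCq-based).
    """
    by1, by2 = calls_by_assay(calls_rep1), calls_by_assay(calls_rep2)
    if set(by1) != set(by2):
        raise ConsistencyError("replicates cover different assay universes")
    union = [a for a in by1 if by1[a].detected or by2[a].detected]
    if not union:
        raise UndefinedMetricError("no assay detected in either replicate")
    double = [a for a in union if by1[a].detected and by2[a].detected]
    pct_double = 100.0 * len(double) / len(union)
    pct_single = 100.0 * (len(union) - len(double)) / len(union)
    pairs = pd.DataFrame(
        {
            "assay_id": double,
            "expr_rep1": [-by1[a].collapsed_cq for a in double],
            "expr_rep2": [-by2[a].collapsed_cq for a in double],
        }
    )
    if len(double) >= 2 and pairs["expr_rep1"].nunique() > 1 and pairs["expr_rep2"].nunique() > 1:
        r = float(stats.pearsonr(pairs["expr_rep1"], pairs["expr_rep2"]).statistic)
    else:
        r = float("nan")
    return pct_double, pct_single, pairs, r


def expression_range(double_positive_expressions) -> float:
    """Span (max - min) of double-positive expression values, log2 units."""
    v = np.asarray(list(double_positive_expressions), dtype=float)
    if v.size < 2:
        raise UndefinedMetricError("expression range needs >= 2 values")
    return float(np.max(v) - np.min(v))


def alc(expr_rep1, expr_rep2) -> float:
    """Area left of the ECDF of absolute replicate differences.

    For a step ECDF the area between the curve and the F-axis over
    F in [0, 1] equals the mean of the differences exactly, with no
    truncation of the d-axis.
    """
    d = np.abs(np.asarray(expr_rep1, dtype=float) - np.asarray(expr_rep2, dtype=float))
    if d.size == 0:
        raise UndefinedMetricError("ALC needs at least one replicate pair")
    return float(np.mean(d))


def alc_by_ecdf_integration(expr_rep1, expr_rep2) -> float:
    """Independent geometric route: integrate the step ECDF directly.

    Area left of the curve = integral of (1 - F(x)) dx from 0 to max(d),
    summed exactly over the ECDF's steps. Used to cross-check :func:`alc`.
    """
    d = np.sort(np.abs(np.asarray(expr_rep1, float) - np.asarray(expr_rep2, float)))
    if d.size == 0:
        raise UndefinedMetricError("ALC needs at least one replicate pair")
    n = d.size
    area = 0.0
    prev = 0.0
    for i, x in enumerate(d):
        survival = 1.0 - i / n  # 1 - F just left of x
        area += (x - prev) * survival
        prev = x
    return float(area)


# ---------------------------------------------------------------------------
# Titration response

def titration_scores(
    expr_A: dict[str, float],
    expr_B: dict[str, float],
    expr_C: dict[str, float],
    expr_D: dict[str, float],
) -> dict[str, float]:
    """Per-assay titration score q in {0, 1/3, 2/3, 1}.

    For mixtures A (100% reference A), C (75%), D (25%), B (0%): if an
    assay expresses higher in A than B its expression must order
    A > C > D > B; if higher in B, the mirrored chain. q is the fraction of
    the three adjacent inequalities (A vs C, C vs D, D vs B, oriented by
    sign(A - B)) that hold strictly; a missing mixture value fails its
    comparisons; assays with A == B or undetected in A or B are skipped.
    """
    scores: dict[str, float] = {}
    for a in expr_A:
        xa, xb = expr_A.get(a), expr_B.get(a)
        if xa is None or xb is None or not np.isfinite(xa) or not np.isfinite(xb):
            continue
        if xa == xb:
            continue
        sign = 1.0 if xa > xb else -1.0
        xc = expr_C.get(a, float("nan"))
        xd = expr_D.get(a, float("nan"))
        chain = ((xa, xc), (xc, xd), (xd, xb))
        n_ok = sum(
            1
            for hi, lo in chain
            if np.isfinite(hi) and np.isfinite(lo) and sign * (hi - lo) > 0
        )
        scores[a] = n_ok / 3.0
    return scores


def titration_auc(scores) -> float:
    """Scale-invariant titration-response AUC in [0, 1].

    Defined as 1 minus the area between the theoretical cumulative
    distribution of q (a unit step at q = 1: every assay titrating
    perfectly) and the empirical one; algebraically this is mean(q).
    """
    q = np.asarray(
        list(scores.values()) if isinstance(scores, dict) else list(scores),
        dtype=float,
    )
    if q.size == 0:
        raise UndefinedMetricError("titration AUC needs at least one score")
    if np.any((q < 0) | (q > 1)):
        raise ChipDataError("titration scores must lie in [0, 1]")
    return float(np.mean(q))


# ---------------------------------------------------------------------------
# Specificity

def cross_reactivity(
    panels: dict[str, list[DetectionCall]],
    family: list[str],
) -> tuple[pd.DataFrame, float, float]:
    """Cross-reactivity matrix (percent) from single-member spike panels.

    ``panels[member]`` holds the detection calls for the run where only
    ``member`` was spiked. For spike i and off-target assay j detected in
    that run, ``CR[i, j] = 100 * 2**(Cq_on - Cq_off)`` — the qPCR signal
    fraction implied by the Cq difference; undetected off-targets score 0;
    the diagonal is fixed at 100. Returns ``(matrix, pct_offtarget_positive,
    median_offtarget_cr)``.
    """
    mat = pd.DataFrame(0.0, index=list(family), columns=list(family))
    off_values = []
    for i in family:
        if i not in panels:
            raise ConsistencyError(f"no spike panel for family member {i!r}")
        by = calls_by_assay(panels[i])
        on = by.get(i)
        if on is None or not on.detected:
            raise UndefinedMetricError(
                f"on-target assay {i!r} not detected in its own spike panel"
            )
        for j in family:
            if j == i:
                mat.loc[i, j] = 100.0
                continue
            off = by.get(j)
            if off is not None and off.detected:
                cr = 100.0 * 2.0 ** (on.collapsed_cq - off.collapsed_cq)
            else:
                cr = 0.0
            mat.loc[i, j] = cr
            off_values.append(cr)
    off = np.asarray(off_values, dtype=float)
    pct_positive = 100.0 * float(np.mean(off > 0)) if off.size else 0.0
    median_cr = float(np.median(off)) if off.size else 0.0
    return mat, pct_positive, median_cr


def ntc_positives(
    ntc_table: CqTable,
    layout: ChipLayout,
    config: Config,
    apply_cq_cutoff: bool = False,
) -> int:
    """Number of target assays showing a positive signal in the
    no-template control.

    Positivity counts any amplification signal in at least
    ``detection_min_wells`` wells; contamination is characteristically late
    (Cq above the quantification cutoff), so the Cq cutoff is not applied
    unless requested.
    """
    calls = call_detection(
        ntc_table, layout, config, apply_cq_cutoff=apply_cq_cutoff, roles=("target",)
    )
    return sum(1 for c in calls if c.detected)


# ---------------------------------------------------------------------------
# Dynamic range

def dynamic_range(
    calls_per_level: list[list[DetectionCall]],
    levels: list[float],
    spiked_assay: str,
    config: Config,
    efficiency: float = 1.0,
) -> tuple[int, float, float]:
    """Longest detected, locally linear run of a spike dilution series.

    ``levels`` are copy numbers, ascending, constant fold spacing. A level
    belongs to the run when the spiked assay is detected there and each
    adjacent Cq step inside the run lies within ``config.dynamic_range_tol``
    (relative) of the theoretical log-law step
    ``log(fold) / log(1 + efficiency)``. Returns ``(orders_of_magnitude,
    low_bound, high_bound)`` with orders = number of levels in the run.
    """
    if len(calls_per_level) != len(levels):
        raise ConsistencyError("one call set per level required")
    if len(levels) < 2:
        raise ChipDataError("dynamic range needs >= 2 levels")
    lv = np.asarray(levels, dtype=float)
    if np.any(lv <= 0) or np.any(np.diff(lv) <= 0):
        raise ChipDataError("levels must be positive and strictly ascending")
    folds = lv[1:] / lv[:-1]
    theory_step = np.log(folds) / np.log(1.0 + efficiency)

    cq = np.full(len(levels), np.nan)
    for i, calls in enumerate(calls_per_level):
        c = calls_by_assay(calls).get(spiked_assay)
        if c is not None and c.detected:
            cq[i] = c.collapsed_cq
    if not np.any(np.isfinite(cq)):
        raise UndefinedMetricError("spiked assay detected at no level")

    # adjacency i -> i+1 is linear if both detected and |ΔCq| matches theory
    tol = config.dynamic_range_tol
    ok = np.zeros(len(levels) - 1, dtype=bool)
    for i in range(len(levels) - 1):
        if np.isfinite(cq[i]) and np.isfinite(cq[i + 1]):
            step = cq[i] - cq[i + 1]  # more copies -> lower Cq
            ok[i] = abs(step - theory_step[i]) <= tol * theory_step[i]

    best_start, best_len = 0, 0
    i = 0
    while i < len(levels):
        if not np.isfinite(cq[i]):
            i += 1
            continue
        j = i
        while j < len(levels) - 1 and ok[j]:
            j += 1
        if j - i + 1 > best_len:
            best_start, best_len = i, j - i + 1
        i = j + 1
    return best_len, float(lv[best_start]), float(lv[best_start + best_len - 1])


# ---------------------------------------------------------------------------
# Report assembly

def build_mirqc_report(
    n_clusters_after_cutoff=None,
    pct_double_positive=None,
    pct_single_positive=None,
    expression_range_log2=None,
    alc=None,
    titration_auc=None,
    pct_offtarget_crossreactive=None,
    median_relative_crossreactivity=None,
    ntc_positive_count=None,
    plasma_detected_count=None,
) -> MiRQCReport:
    """Assemble the platform performance report; every constituent must be
    present or a :class:`PartialReportError` names the absent fields."""
    values = {
        "n_clusters_after_cutoff": n_clusters_after_cutoff,
        "pct_double_positive": pct_double_positive,
        "pct_single_positive": pct_single_positive,
        "expression_range_log2": expression_range_log2,
        "alc": alc,
        "titration_auc": titration_auc,
        "pct_offtarget_crossreactive": pct_offtarget_crossreactive,
        "median_relative_crossreactivity": median_relative_crossreactivity,
        "ntc_positive_count": ntc_positive_count,
        "plasma_detected_count": plasma_detected_count,
    }
    missing = [k for k, v in values.items() if v is None]
    if missing:
        raise PartialReportError(missing)
    return MiRQCReport(**values)
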