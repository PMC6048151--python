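"""End-to-end pipelines: the full synthetic QC battery and the cohort
classification chain.

Seeding: one global seed enters ``numpy.random.SeedSequence``; each stage
draws its own child stream in a fixed order (titration, reproducibility,
efficiency, spike series, specificity, NTC, plasma, cohort), so stages can
be rerun independently yet bit-reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chipio, preprocess, qcmetrics, synthdata
from .chipio import ChipLayout, Config, CqTable, FIVE_FACTOR_IDS, SampleSheet
from .classify import ClassifierMetrics, ConfusionMatrix, confusion_metrics, cross_validate
from .errors import UndefinedMetricError
from .qcmetrics import EfficiencyFit, MiRQCReport
from .synthdata import AssayTruth, SimConfig

STAGES = (
    "titration",
    "reproducibility",
    "efficiency",
    "spike",
    "specificity",
    "ntc",
    "plasma",
    "cohort",
)

#: 10-fold spike levels in copies per nanowell; the platform's knee and
#: saturation bracket the inner 80 ... 8e7 span.
DEFAULT_SPIKE_LEVELS = tuple(8.0 * 10.0 ** i for i in range(9))

LET7_FAMILY = ("hsa-let-7a-5p", "hsa-let-7b-5p", "hsa-let-7c-5p")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES) + 1)
    rngs = {name: np.random.default_rng(ss) for name, ss in zip(STAGES, children)}
    rngs["truths"] = np.random.default_rng(children[-1])
    return rngs


def specificity_layout(base: ChipLayout) -> ChipLayout:
    """Rename the first three target clusters to the let-7 family so the
    cross-hybridization panel has named members."""
    clusters = list(base.clusters)
    for i, name in enumerate(LET7_FAMILY):
        old = clusters[i]
        clusters[i] = chipio.Cluster(name, old.role, old.well_ids)
    return ChipLayout(base.chip_id, base.wells_total, tuple(clusters))


@dataclass
class BatteryData:
    """All raw synthetic inputs of one QC battery run."""

    seed: int
    sim: SimConfig
    layout: ChipLayout
    spec_layout: ChipLayout
    truths: dict[str, AssayTruth]
    spec_truths: dict[str, AssayTruth]
    titration: dict[str, CqTable]
    replicates: tuple[CqTable, CqTable]
    spike_tables: list[CqTable]
    spike_levels: tuple[float, ...]
    spiked_assay: str
    specificity_panels: list[CqTable]
    ntc: CqTable
    plasma: CqTable


@dataclass
class BatteryResult:
    report: MiRQCReport
    efficiency_fits: dict[str, EfficiencyFit]
    replicate_r: float
    dynamic_range_orders: int
    dynamic_range_bounds: tuple[float, float]
    cross_matrix: object


def simulate_battery(
    seed: int,
    sim: SimConfig | None = None,
    layout: ChipLayout | None = None,
) -> BatteryData:
    sim = sim or SimConfig(rng_seed=seed)
    layout = layout or chipio.build_default_layout(n_targets=sim.n_assays,
                                                   wells_per_cluster=sim.wells_per_cluster)
    rngs = stage_rngs(seed)
    truths = synthdata.default_truths(layout, rngs["truths"], sim)

    titration = synthdata.simulate_titration_runs(truths, layout, sim, rngs["titration"])

    rep_copies = {a: t.copies_A for a, t in truths.items()}
    rep1 = synthdata.simulate_chip_run(
        rep_copies, layout, sim, rngs["reproducibility"], sample_id="ref-A-rep1",
        truths=truths)
    rep2 = synthdata.simulate_chip_run(
        rep_copies, layout, sim, rngs["reproducibility"], sample_id="ref-A-rep2",
        truths=truths)

    spiked = layout.target_ids[0]
    spike_tables = synthdata.simulate_spike_series(
        truths, list(DEFAULT_SPIKE_LEVELS), layout, sim, rngs["spike"],
        spiked_assay=spiked)

    spec_layout = specificity_layout(layout)
    spec_truths = dict(truths)
    for i, name in enumerate(LET7_FAMILY):
        old_id = layout.target_ids[i]
        t = spec_truths.pop(old_id)
        spec_truths[name] = AssayTruth(name, t.copies_A, t.copies_B, t.efficiency,
                                       t.intercept)
    panels = synthdata.simulate_specificity_panel(
        list(LET7_FAMILY), np.eye(3), spec_truths, spec_layout, sim,
        rngs["specificity"])

    ntc = synthdata.simulate_ntc_run(truths, layout, sim, rngs["ntc"])

    plasma_copies = {a: t.copies_A * 1e-2 for a, t in truths.items()}
    for name, _ in chipio.DEFAULT_CONTROLS:
        plasma_copies[name] = truths[name].copies_A  # spiked controls stay abundant
    plasma = synthdata.simulate_chip_run(
        plasma_copies, layout, sim, rngs["plasma"], sample_id="plasma", truths=truths)

    return BatteryData(
        seed=seed, sim=sim, layout=layout, spec_layout=spec_layout, truths=truths,
        spec_truths=spec_truths, titration=titration, replicates=(rep1, rep2),
        spike_tables=spike_tables, spike_levels=DEFAULT_SPIKE_LEVELS,
        spiked_assay=spiked, specificity_panels=panels, ntc=ntc, plasma=plasma,
    )


def titration_expressions(
    titration: dict[str, CqTable], layout: ChipLayout, config: Config
) -> dict[str, dict[str, float]]:
    """Normalized expression (-ΔCq) per mixture, per target assay."""
    out = {}
    for name, table in titration.items():
        calls = qcmetrics.call_detection(table, layout, config)
        prof = preprocess.normalize_profile(
            calls, list(FIVE_FACTOR_IDS), sample_id=table.sample_id,
            assay_universe=layout.target_ids, mode="five_factor")
        out[name] = {a: -v for a, v in prof.values.items() if np.isfinite(v)}
    return out


def analyze_battery(data: BatteryData, config: Config | None = None) -> BatteryResult:
    config = config or Config()

    expr = titration_expressions(data.titration, data.layout, config)
    scores = qcmetrics.titration_scores(expr["A"], expr["B"], expr["C"], expr["D"])
    auc = qcmetrics.titration_auc(scores)

    rep1, rep2 = data.replicates
    calls1 = qcmetrics.call_detection(rep1, data.layout, config, roles=("target",))
    calls2 = qcmetrics.call_detection(rep2, data.layout, config, roles=("target",))
    pct_double, pct_single, pairs, r = qcmetrics.replicate_concordance(calls1, calls2)
    n_after_cutoff = sum(
        1 for a, b in zip(calls1, calls2) if a.detected or b.detected
    )
    alc_value = qcmetrics.alc(pairs["expr_rep1"], pairs["expr_rep2"])
    all_expr = np.concatenate([pairs["expr_rep1"], pairs["expr_rep2"]])
    range_log2 = qcmetrics.expression_range(all_expr)

    # standard curves need ground truth to regenerate dilution series; a
    # bundle loaded from disk carries none, so fits are skipped there and
    # the dynamic-range theory step falls back to the nominal E = 1
    eff_fits = fit_battery_efficiencies(data, config) if data.truths else {}

    spike_calls = [
        qcmetrics.call_detection(t, data.layout, config) for t in data.spike_tables
    ]
    dr_efficiency = (
        data.truths[data.spiked_assay].efficiency if data.truths else 1.0
    )
    orders, low, high = qcmetrics.dynamic_range(
        spike_calls, list(data.spike_levels), data.spiked_assay, config,
        efficiency=dr_efficiency)

    panel_calls = {
        member: qcmetrics.call_detection(t, data.spec_layout, config)
        for member, t in zip(LET7_FAMILY, data.specificity_panels)
    }
    cross, pct_cross, median_cr = qcmetrics.cross_reactivity(
        panel_calls, list(LET7_FAMILY))

    ntc_count = qcmetrics.ntc_positives(data.ntc, data.layout, config)

    plasma_calls = qcmetrics.call_detection(
        data.plasma, data.layout, config, roles=("target",))
    plasma_count = sum(1 for c in plasma_calls if c.detected)

    report = qcmetrics.build_mirqc_report(
        n_clusters_after_cutoff=n_after_cutoff,
        pct_double_positive=pct_double,
        pct_single_positive=pct_single,
        expression_range_log2=range_log2,
        alc=alc_value,
        titration_auc=auc,
        pct_offtarget_crossreactive=pct_cross,
        median_relative_crossreactivity=median_cr,
        ntc_positive_count=ntc_count,
        plasma_detected_count=plasma_count,
    )
    return BatteryResult(
        report=report,
        efficiency_fits=eff_fits,
        replicate_r=r,
        dynamic_range_orders=orders,
        dynamic_range_bounds=(low, high),
        cross_matrix=cross,
    )


def fit_battery_efficiencies(
    data: BatteryData, config: Config, n_assays: int = 9, n_points: int = 5
) -> dict[str, EfficiencyFit]:
    """Standard-curve efficiency for representative assays: 3-fold
    dilution series of reference A, simulated per level with the battery's
    efficiency stage stream."""
    rng = stage_rngs(data.seed)["efficiency"]
    return fit_dilution_efficiencies(
        data.truths, data.layout, config, data.sim, rng,
        assays=data.layout.target_ids[:n_assays], n_points=n_points)


def fit_dilution_efficiencies(
    truths, layout, config, sim, rng, assays, n_points=5, fold=3.0
) -> dict[str, EfficiencyFit]:
    fits = {}
    dilutions = [fold ** -i for i in range(n_points)]
    tables = []
    for i, d in enumerate(dilutions):
        copies = {a: t.copies_A * d for a, t in truths.items()}
        tables.append(
            synthdata.simulate_chip_run(
                copies, layout, sim, rng, sample_id=f"dilution-{i}", truths=truths))
    calls = [qcmetrics.call_detection(t, layout, config) for t in tables]
    for a in assays:
        series = []
        for d, cs in zip(dilutions, calls):
            c = qcmetrics.calls_by_assay(cs)[a]
            if c.detected:
                series.append((np.log10(d), c.collapsed_cq))
        if len(series) >= 3:
            fits[a] = qcmetrics.fit_efficiency(series)
    return fits


# ---------------------------------------------------------------------------
# Cohort pipeline

@dataclass
class CohortRun:
    tables: list[CqTable]
    sheet: SampleSheet
    layout: ChipLayout


def simulate_cohort_run(
    seed: int, sim: SimConfig | None = None, layout: ChipLayout | None = None
) -> CohortRun:
    sim = sim or SimConfig(rng_seed=seed)
    layout = layout or chipio.build_default_layout(n_targets=sim.n_assays,
                                                   wells_per_cluster=sim.wells_per_cluster)
    rngs = stage_rngs(seed)
    truths = synthdata.default_truths(layout, rngs["truths"], sim)
    tables, sheet = synthdata.simulate_cohort(truths, layout, sim, rngs["cohort"])
    return CohortRun(tables=tables, sheet=sheet, layout=layout)


def classify_cohort(
    run: CohortRun, config: Config | None = None, seed: int = 0
) -> tuple[object, ConfusionMatrix, ClassifierMetrics, int]:
    """Preprocess the cohort and cross-validate the classifier.

    Returns ``(predictions, confusion_matrix, metrics, n_excluded_hemolysis)``.
    """
    config = config or Config()
    cohort = preprocess.build_cohort_matrix(run.tables, run.sheet, run.layout, config)
    preds, cm = cross_validate(cohort, k=config.cv_folds, seed=seed, C=config.svm_cost)
    return preds, cm, confusion_metrics(cm), cohort.n_excluded_hemolysis
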