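"""Synthetic nanowell chip-run generator.

Emulates the statistical structure the downstream analysis assumes:

* a copy-number -> Cq law ``Cq = intercept - log(copies) / log(1 + E)``
  with per-assay amplification efficiency E (E = 1 doubles template every
  cycle, so one Cq cycle is one log2 unit);
* Gaussian technical noise on Cq (default sd 0.20 cycles);
* stochastic dropout with detection probability
  ``p(copies) = 1 - exp(-copies / phi)`` — a one-parameter smooth detection
  curve consistent with Poisson occupancy of 20-nl wells; the default
  ``phi = 40`` copies places the detection knee just below the 80
  copies/nanowell floor the emulated platform resolves;
* saturation: above ``saturation_copies`` the measured Cq stops decreasing;
* reference-RNA titration mixtures, 10-fold spike-in dilution series,
  cross-hybridization spike panels on a carrier background, no-template
  controls with a small contamination probability, and a two-class plasma
  cohort with differentially expressed assays.

All randomness flows through one seeded ``numpy.random.Generator``; the
operation order is fixed, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chipio import (
    ChipLayout,
    Config,
    CqTable,
    MAX_CYCLES,
    SampleSheet,
    build_default_layout,
)
from .errors import ChipDataError, ConfigError, ConsistencyError


@dataclass(frozen=True)
class AssayTruth:
    """Ground truth for one assay: reference copy numbers and PCR behaviour.

    ``intercept`` is the noise-free Cq at 1 copy per nanowell.
    """

    assay_id: str
    copies_A: float
    copies_B: float
    efficiency: float
    intercept: float

    def __post_init__(self):
        if self.copies_A < 0 or self.copies_B < 0:
            raise ConfigError("copies must be >= 0")
        if not (0.5 < self.efficiency <= 1.2):
            raise ConfigError(f"efficiency {self.efficiency} outside (0.5, 1.2]")
        if not (25 < self.intercept < 45):
            raise ConfigError(f"intercept {self.intercept} outside (25, 45)")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_assays: int = 164
    wells_per_cluster: int = 9
    cq_noise_sd: float = 0.20
    detection_scale_phi: float = 40.0
    titration_fractions: tuple[float, ...] = (1.0, 0.75, 0.25, 0.0)
    saturation_copies: float = 1e8
    p_ntc: float = 0.10
    n_case: int = 38
    n_control: int = 84
    n_repeats: int = 2
    n_differential: int = 20
    effect_size_delta_cq: float = 3.0
    bio_noise_sd: float = 0.75
    baseline_log2_sd: float = 1.5
    hemolysis_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if any(not (0.0 <= f <= 1.0) for f in self.titration_fractions):
            raise ConfigError("titration fractions must lie in [0, 1]")
        for name in ("detection_scale_phi", "saturation_copies"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cq_noise_sd < 0 or self.bio_noise_sd < 0:
            raise ConfigError("noise sds must be >= 0")
        if not (0.0 <= self.p_ntc <= 1.0):
            raise ConfigError("p_ntc must lie in [0, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("cohort sizes must be >= 1")
        if self.n_differential > self.n_assays:
            raise ConfigError("n_differential cannot exceed n_assays")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        import json

        with open(path) as fh:
            raw = json.load(fh)
        if "titration_fractions" in raw:
            raw["titration_fractions"] = tuple(raw["titration_fractions"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None


def copies_to_cq(
    copies: float,
    truth: AssayTruth,
    noise_sd: float,
    rng: np.random.Generator,
    detection_scale_phi: float = 40.0,
    saturation_copies: float = 1e8,
) -> float:
    """One well's measurement: Cq in cycles, or NaN for no amplification.

    Deterministic core ``Cq* = intercept - log(min(copies, sat)) / log(1+E)``;
    the well fails to amplify with probability ``exp(-copies/phi)`` (always,
    for zero copies).
    """
    if copies < 0:
        raise ChipDataError("copies must be >= 0")
    if copies == 0:
        return np.nan
    p_detect = 1.0 - np.exp(-copies / detection_scale_phi)
    if rng.random() >= p_detect:
        return np.nan
    eff_copies = min(copies, saturation_copies)
    cq = truth.intercept - np.log(eff_copies) / np.log(1.0 + truth.efficiency)
    if noise_sd > 0:
        cq += rng.normal(0.0, noise_sd)
    return float(np.clip(cq, np.nextafter(0.0, 1.0), MAX_CYCLES))


def mix_titration(copies_A: float, copies_B: float, fraction_A: float) -> float:
    """Mixing RNA masses mixes molecule counts: linear on the copy scale."""
    if copies_A < 0 or copies_B < 0:
        raise ChipDataError("copies must be >= 0")
    if not (0.0 <= fraction_A <= 1.0):
        raise ChipDataError(f"fraction_A {fraction_A} outside [0, 1]")
    return fraction_A * copies_A + (1.0 - fraction_A) * copies_B


def default_truths(
    layout: ChipLayout, rng: np.random.Generator, sim: SimConfig
) -> dict[str, AssayTruth]:
    """Plausible per-assay ground truth for the emulated panel.

    Target abundances span several log10 of copies/nanowell (plasma miRNAs
    vary over a wide dynamic range); controls are abundant so they are
    always detected. Efficiencies draw uniformly from 0.90-1.10.
    """
    truths: dict[str, AssayTruth] = {}
    for cl in layout.clusters:
        eff = float(rng.uniform(0.90, 1.10))
        intercept = float(rng.uniform(34.0, 38.0))
        if cl.role == "target":
            log10_a = float(rng.uniform(1.0, 6.0))
            log10_b = log10_a + float(rng.normal(0.0, 1.0))
            copies_a, copies_b = 10.0 ** log10_a, 10.0 ** log10_b
        else:
            copies_a = copies_b = 1e5
        truths[cl.assay_id] = AssayTruth(cl.assay_id, copies_a, copies_b, eff, intercept)
    return truths


def simulate_chip_run(
    copies_by_assay: dict[str, float],
    layout: ChipLayout,
    sim: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    is_ntc: bool = False,
    truths: dict[str, AssayTruth] | None = None,
) -> CqTable:
    """One chip run: 9 independent well draws per cluster.

    For an NTC run every target sees zero copies, and each assay
    independently carries a contamination event with probability ``p_ntc``:
    the whole cluster then amplifies late, at Cq ~ Uniform(33, 39) plus
    per-well noise.
    """
    if truths is None:
        raise ConsistencyError("per-assay truths are required")
    missing = [cl.assay_id for cl in layout.clusters if cl.assay_id not in copies_by_assay]
    if missing:
        raise ConsistencyError(f"no copy number for assays: {missing}")
    rows = []
    for cl in layout.clusters:
        truth = truths[cl.assay_id]
        copies = copies_by_assay[cl.assay_id]
        contaminated_cq = None
        if is_ntc and rng.random() < sim.p_ntc:
            contaminated_cq = rng.uniform(33.0, 39.0)
        for w in cl.well_ids:
            if contaminated_cq is not None:
                cq = contaminated_cq + (
                    rng.normal(0.0, sim.cq_noise_sd) if sim.cq_noise_sd > 0 else 0.0
                )
                cq = float(np.clip(cq, np.nextafter(0.0, 1.0), MAX_CYCLES))
            else:
                cq = copies_to_cq(
                    copies, truth, sim.cq_noise_sd, rng,
                    detection_scale_phi=sim.detection_scale_phi,
                    saturation_copies=sim.saturation_copies,
                )
            rows.append({"well_id": w, "assay_id": cl.assay_id, "cq": cq})
    data = pd.DataFrame(rows, columns=["well_id", "assay_id", "cq"])
    return CqTable(sample_id=sample_id, chip_id=layout.chip_id, data=data)


def simulate_titration_runs(
    truths: dict[str, AssayTruth],
    layout: ChipLayout,
    sim: SimConfig,
    rng: np.random.Generator,
) -> dict[str, CqTable]:
    """Chip runs for the four reference mixtures A (100% ref-A), C (75%),
    D (25%), B (0%)."""
    names = ["A", "C", "D", "B"]
    out: dict[str, CqTable] = {}
    for name, frac in zip(names, sim.titration_fractions):
        copies = {
            a: mix_titration(t.copies_A, t.copies_B, frac) for a, t in truths.items()
        }
        out[name] = simulate_chip_run(
            copies, layout, sim, rng, sample_id=f"titration-{name}", truths=truths
        )
    return out


def simulate_spike_series(
    truths: dict[str, AssayTruth],
    levels: list[float],
    layout: ChipLayout,
    sim: SimConfig,
    rng: np.random.Generator,
    spiked_assay: str | None = None,
) -> list[CqTable]:
    """One chip run per spike level; only the spiked assay varies, the
    background stays at reference-A truth."""
    if len(levels) == 0:
        raise ChipDataError("empty spike levels")
    if any(l <= 0 for l in levels):
        raise ChipDataError("spike levels must be strictly positive")
    if list(levels) != sorted(levels):
        raise ChipDataError("spike levels must be sorted ascending")
    if spiked_assay is None:
        spiked_assay = layout.target_ids[0]
    tables = []
    for i, level in enumerate(levels):
        copies = {a: t.copies_A for a, t in truths.items()}
        copies[spiked_assay] = float(level)
        tables.append(
            simulate_chip_run(
                copies, layout, sim, rng, sample_id=f"spike-{i}", truths=truths
            )
        )
    return tables


def simulate_specificity_panel(
    family: list[str],
    cross_matrix: np.ndarray,
    truths: dict[str, AssayTruth],
    layout: ChipLayout,
    sim: SimConfig,
    rng: np.random.Generator,
    spike_copies: float = 1e5,
) -> list[CqTable]:
    """One chip run per spiked family member on a carrier-only background.

    In run i (member i spiked), assay j receives
    ``spike_copies * cross_matrix[i, j]`` copies; everything else sees zero
    (the carrier RNA holds no panel targets).
    """
    cross = np.asarray(cross_matrix, dtype=float)
    if cross.ndim != 2 or cross.shape[0] != cross.shape[1] or cross.shape[0] != len(family):
        raise ChipDataError("cross_matrix must be square over the family")
    tables = []
    for i, member in enumerate(family):
        copies = {cl.assay_id: 0.0 for cl in layout.clusters}
        for j, assay in enumerate(family):
            copies[assay] = spike_copies * cross[i, j]
        tables.append(
            simulate_chip_run(
                copies, layout, sim, rng, sample_id=f"specificity-{member}",
                truths=truths,
            )
        )
    return tables


def simulate_ntc_run(
    truths: dict[str, AssayTruth],
    layout: ChipLayout,
    sim: SimConfig,
    rng: np.random.Generator,
) -> CqTable:
    """No-template control: zero copies everywhere plus contamination."""
    copies = {cl.assay_id: 0.0 for cl in layout.clusters}
    return simulate_chip_run(
        copies, layout, sim, rng, sample_id="ntc", is_ntc=True, truths=truths
    )


def simulate_cohort(
    truths: dict[str, AssayTruth],
    layout: ChipLayout,
    sim: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[CqTable], SampleSheet]:
    """Two-class plasma cohort with chip repeats per subject.

    Per-subject baseline copy numbers draw log-normally around the assay
    reference; in cases, ``n_differential`` target assays shift by
    ``effect_size_delta_cq`` cycles (2^effect on the copy scale), with a
    per-assay direction randomized once and held fixed across subjects.
    Subject-level biological noise (``bio_noise_sd`` cycles) is shared by a
    subject's repeat chips; chip-level technical noise comes from
    ``cq_noise_sd`` in the well draws. A ``hemolysis_fraction`` of samples
    draws absorbances failing the A414/A375 > 2 rule.
    """
    targets = layout.target_ids
    diff_assays = list(rng.choice(targets, size=sim.n_differential, replace=False))
    directions = {a: (1.0 if rng.random() < 0.5 else -1.0) for a in diff_assays}

    n_subjects = sim.n_case + sim.n_control
    labels = ["OSCC"] * sim.n_case + ["HD"] * sim.n_control
    tables: list[CqTable] = []
    sheet_rows = []
    for s in range(n_subjects):
        subject_id = f"subj-{s + 1:03d}"
        label = labels[s]
        # subject-level biology: log2-scale deviations shared across repeats
        base_dev = rng.normal(0.0, sim.baseline_log2_sd, size=len(targets))
        bio_dev = rng.normal(0.0, sim.bio_noise_sd, size=len(targets))
        copies = {}
        for a, t in truths.items():
            copies[a] = t.copies_A
        for i, a in enumerate(targets):
            log2_shift = base_dev[i] + bio_dev[i]
            if label == "OSCC" and a in directions:
                log2_shift += directions[a] * sim.effect_size_delta_cq
            copies[a] = truths[a].copies_A * 2.0 ** log2_shift
        # hemolysis is a property of the subject's plasma, shared by repeats
        hemolyzed = rng.random() < sim.hemolysis_fraction
        a375 = float(rng.uniform(0.5, 1.5))
        ratio = float(rng.uniform(2.2, 3.5)) if hemolyzed else float(rng.uniform(0.8, 1.8))
        for rep in range(sim.n_repeats):
            sample_id = f"{subject_id}-r{rep + 1}"
            tables.append(
                simulate_chip_run(
                    copies, layout, sim, rng, sample_id=sample_id, truths=truths
                )
            )
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject_id,
                    "class_label": label,
                    "replicate_index": rep + 1,
                    "a414": round(ratio * a375, 4),
                    "a375": round(a375, 4),
                    "rna_input_ng": 0.2,
                }
            )
    sheet = SampleSheet(pd.DataFrame(sheet_rows, columns=SampleSheet.COLUMNS))
    return tables, sheet
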