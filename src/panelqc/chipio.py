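"""Data model and file formats for nanowell qPCR chip runs.

A chip is a grid of nanowells (2500 on the emulated chip). Each assay — a
miRNA target or a control — occupies a fixed *cluster* of replicate wells
(9 on the emulated chip). A chip run yields one Cq (quantification cycle)
per well, or an explicit no-amplification flag.

File formats are plain CSV:

* layout:    ``chip_id,assay_id,role,well_id``
* Cq table:  ``sample_id,chip_id,well_id,assay_id,cq`` with the exact token
  ``NA`` encoding no amplification
* sample sheet: ``sample_id,subject_id,class_label,replicate_index,a414,a375,rna_input_ng``

No-amplification is a flag (NaN in memory, "NA" on disk), never a sentinel
Cq such as 40: downstream imputation must see true missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    ConsistencyError,
    FormatError,
    LayoutError,
    RangeError,
)

MAX_CYCLES = 40.0

ROLES = frozenset(
    {"target", "endogenous_control", "rt_control", "qpcr_control", "ntc"}
)

#: Control assays of the emulated panel. The first five are the named
#: normalization factors; the last two are generator-defined placeholders.
DEFAULT_CONTROLS = (
    ("hsa-RNU6B", "endogenous_control"),
    ("hsa-RNU43", "endogenous_control"),
    ("hsa-18s-rRNA", "endogenous_control"),
    ("RT-control", "rt_control"),
    ("qPCR-control", "qpcr_control"),
    ("spike-control-1", "endogenous_control"),
    ("spike-control-2", "endogenous_control"),
)

FIVE_FACTOR_IDS = ("hsa-RNU6B", "hsa-RNU43", "hsa-18s-rRNA", "RT-control", "qPCR-control")
PROCESS_CONTROL_IDS = ("RT-control", "qPCR-control")


@dataclass(frozen=True)
class Cluster:
    """One assay's replicate-well group on a chip."""

    assay_id: str
    role: str
    well_ids: tuple[int, ...]

    def __post_init__(self):
        if self.role not in ROLES:
            raise FormatError(f"unknown role {self.role!r} for assay {self.assay_id!r}")
        if len(self.well_ids) < 1:
            raise LayoutError(f"cluster {self.assay_id!r} has no wells")


@dataclass(frozen=True)
class ChipLayout:
    """Maps each assay to its replicate-well cluster.

    Well indices are 0-based in a flat row-major grid (50x50 for the
    2500-well chip).
    """

    chip_id: str
    wells_total: int
    clusters: tuple[Cluster, ...]

    def __post_init__(self):
        if self.wells_total <= 0:
            raise LayoutError("wells_total must be positive")
        seen: dict[int, str] = {}
        for cl in self.clusters:
            for w in cl.well_ids:
                if not (0 <= w < self.wells_total):
                    raise LayoutError(
                        f"well {w} of assay {cl.assay_id!r} outside [0, {self.wells_total})"
                    )
                if w in seen:
                    raise LayoutError(
                        f"well {w} assigned to both {seen[w]!r} and {cl.assay_id!r}"
                    )
                seen[w] = cl.assay_id
        ids = [cl.assay_id for cl in self.clusters]
        if len(set(ids)) != len(ids):
            raise LayoutError("duplicate assay_id in layout")

    @property
    def assay_ids(self) -> list[str]:
        return [cl.assay_id for cl in self.clusters]

    @property
    def target_ids(self) -> list[str]:
        return [cl.assay_id for cl in self.clusters if cl.role == "target"]

    def cluster(self, assay_id: str) -> Cluster:
        for cl in self.clusters:
            if cl.assay_id == assay_id:
                return cl
        raise ConsistencyError(f"assay {assay_id!r} not in layout {self.chip_id!r}")

    def roles(self, role: str) -> list[str]:
        return [cl.assay_id for cl in self.clusters if cl.role == role]

    def require_process_controls(self) -> None:
        """Process-control normalization needs RT and qPCR control clusters."""
        if not self.roles("rt_control") or not self.roles("qpcr_control"):
            raise LayoutError(
                "process_controls normalization requires rt_control and "
                "qpcr_control clusters in the layout"
            )


def build_default_layout(
    n_targets: int = 164,
    wells_per_cluster: int = 9,
    wells_total: int = 2500,
    chip_id: str = "chip-1",
) -> ChipLayout:
    """The emulated panel: ``n_targets`` miRNA assays plus 7 controls,
    each on a ``wells_per_cluster``-well cluster, assigned consecutively
    on the flat grid."""
    clusters = []
    w = 0
    for i in range(n_targets):
        ids = tuple(range(w, w + wells_per_cluster))
        clusters.append(Cluster(f"mir-{i + 1:03d}", "target", ids))
        w += wells_per_cluster
    for name, role in DEFAULT_CONTROLS:
        ids = tuple(range(w, w + wells_per_cluster))
        clusters.append(Cluster(name, role, ids))
        w += wells_per_cluster
    if w > wells_total:
        raise LayoutError(
            f"{w} wells required but chip has only {wells_total}"
        )
    return ChipLayout(chip_id=chip_id, wells_total=wells_total, clusters=tuple(clusters))


@dataclass
class CqTable:
    """Per-well raw Cq measurements for one sample on one chip.

    ``data`` has columns ``well_id`` (int), ``assay_id`` (str), ``cq``
    (float; NaN flags no amplification). Each well appears at most once.
    """

    sample_id: str
    chip_id: str
    data: pd.DataFrame

    def __post_init__(self):
        required = ["well_id", "assay_id", "cq"]
        if list(self.data.columns) != required:
            self.data = self.data.loc[:, required]
        self.data = self.data.reset_index(drop=True)
        cq = self.data["cq"].to_numpy(dtype=float)
        finite = np.isfinite(cq)
        if np.any((cq[finite] <= 0) | (cq[finite] > MAX_CYCLES)):
            bad = cq[finite][(cq[finite] <= 0) | (cq[finite] > MAX_CYCLES)][0]
            raise RangeError(f"cq={bad} outside (0, {MAX_CYCLES}]")
        if self.data["well_id"].duplicated().any():
            w = int(self.data.loc[self.data["well_id"].duplicated(), "well_id"].iloc[0])
            raise ConsistencyError(f"well {w} appears more than once")

    def validate_against(self, layout: ChipLayout) -> "CqTable":
        pairs = {
            (int(w), a)
            for cl in layout.clusters
            for w, a in ((wid, cl.assay_id) for wid in cl.well_ids)
        }
        for w, a in zip(self.data["well_id"], self.data["assay_id"]):
            if (int(w), a) not in pairs:
                raise ConsistencyError(
                    f"(well {int(w)}, assay {a!r}) not in layout {layout.chip_id!r}"
                )
        return self

    def cluster_cqs(self, cluster: Cluster) -> np.ndarray:
        """Cq values (NaN = no amplification) for the cluster's wells."""
        sub = self.data[self.data["assay_id"] == cluster.assay_id]
        return sub["cq"].to_numpy(dtype=float)

    def __eq__(self, other):
        if not isinstance(other, CqTable):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.chip_id == other.chip_id
            and self.data.equals(other.data)
        )


@dataclass
class SampleSheet:
    """Cohort metadata: one row per chip run (sample)."""

    data: pd.DataFrame

    COLUMNS = [
        "sample_id",
        "subject_id",
        "class_label",
        "replicate_index",
        "a414",
        "a375",
        "rna_input_ng",
    ]

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        self.data = self.data.loc[:, self.COLUMNS].reset_index(drop=True)
        if self.data["sample_id"].duplicated().any():
            raise ConsistencyError("duplicate sample_id in sample sheet")
        for col in ("a414", "a375"):
            v = self.data[col].to_numpy(dtype=float)
            if np.any(v[np.isfinite(v)] < 0):
                raise RangeError(f"negative absorbance in column {col}")


@dataclass
class Config:
    """Analysis configuration.

    cq_cutoff
        Detection requires Cq strictly below this cycle (default 34).
    detection_min_wells
        Minimum amplified wells per cluster for a detection call (default
        5 of 9, a majority vote).
    well_collapse
        How replicate wells collapse to one Cq: "median" (default) or "mean".
    normalization_factors
        Assay ids whose mean Cq is subtracted to form ΔCq.
    cv_folds
        Stratified cross-validation folds (default 10).
    svm_cost
        Misclassification cost C of the linear maximum-margin classifier.
    dynamic_range_tol
        Relative tolerance on adjacent ΔCq vs the theoretical dilution step
        when assessing local linearity (default 0.30).
    """

    cq_cutoff: float = 34.0
    detection_min_wells: int = 5
    well_collapse: str = "median"
    normalization_factors: tuple[str, ...] = PROCESS_CONTROL_IDS
    cv_folds: int = 10
    svm_cost: float = 1.0
    dynamic_range_tol: float = 0.30
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.cq_cutoff < MAX_CYCLES):
            raise ConfigError(f"cq_cutoff must lie in (0, {MAX_CYCLES})")
        if self.detection_min_wells < 1:
            raise ConfigError("detection_min_wells must be >= 1")
        if self.well_collapse not in ("median", "mean"):
            raise ConfigError(f"unknown well_collapse {self.well_collapse!r}")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.svm_cost <= 0:
            raise ConfigError("svm_cost must be positive")

    @classmethod
    def from_json(cls, path) -> "Config":
        with open(path) as fh:
            raw = json.load(fh)
        try:
            if "normalization_factors" in raw:
                raw["normalization_factors"] = tuple(raw["normalization_factors"])
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_json(self, path) -> None:
        d = self.__dict__.copy()
        d["normalization_factors"] = list(d["normalization_factors"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


# ---------------------------------------------------------------------------
# CSV readers / writers

def read_chip_layout(path) -> ChipLayout:
    df = pd.read_csv(path, dtype={"chip_id": str, "assay_id": str, "role": str})
    required = {"chip_id", "assay_id", "role", "well_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"layout CSV needs columns {sorted(required)}")
    if df.empty:
        raise FormatError("empty layout file")
    chip_ids = df["chip_id"].unique()
    if len(chip_ids) != 1:
        raise FormatError(f"layout file mixes chips: {list(chip_ids)}")
    clusters = []
    for (assay, role), grp in df.groupby(["assay_id", "role"], sort=False):
        clusters.append(Cluster(assay, role, tuple(int(w) for w in grp["well_id"])))
    wells_total = int(df.attrs.get("wells_total", 2500))
    return ChipLayout(chip_id=str(chip_ids[0]), wells_total=wells_total,
                      clusters=tuple(clusters))


def write_chip_layout(layout: ChipLayout, path) -> None:
    rows = [
        {"chip_id": layout.chip_id, "assay_id": cl.assay_id, "role": cl.role,
         "well_id": w}
        for cl in layout.clusters
        for w in cl.well_ids
    ]
    pd.DataFrame(rows, columns=["chip_id", "assay_id", "role", "well_id"]).to_csv(
        path, index=False
    )


def read_cq_table(path, layout: ChipLayout | None = None) -> CqTable:
    """Read one sample's Cq table. The exact token ``NA`` flags
    no amplification; any other non-numeric token is a format error."""
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "chip_id": str, "assay_id": str, "cq": str},
        keep_default_na=False,
    )
    required = {"sample_id", "chip_id", "well_id", "assay_id", "cq"}
    if not required.issubset(df.columns):
        raise FormatError(f"Cq CSV needs columns {sorted(required)}")
    cq = np.empty(len(df))
    for i, tok in enumerate(df["cq"]):
        if tok == "NA":
            cq[i] = np.nan
        else:
            try:
                cq[i] = float(tok)
            except ValueError:
                raise FormatError(f"unparseable cq token {tok!r}") from None
    sample_ids = df["sample_id"].unique() if len(df) else ["sample"]
    chip_ids = df["chip_id"].unique() if len(df) else ["chip"]
    if len(sample_ids) != 1 or len(chip_ids) != 1:
        raise FormatError("Cq table file must hold exactly one (sample, chip)")
    table = CqTable(
        sample_id=str(sample_ids[0]),
        chip_id=str(chip_ids[0]),
        data=pd.DataFrame(
            {"well_id": df["well_id"].astype(int) if len(df) else pd.Series([], dtype=int),
             "assay_id": df["assay_id"], "cq": cq}
        ),
    )
    if layout is not None:
        table.validate_against(layout)
    return table


def write_cq_table(table: CqTable, path) -> None:
    """Values print at 4 decimals; read(write(x)) round-trips exactly for
    tables at that precision."""
    out = table.data.copy()
    out.insert(0, "chip_id", table.chip_id)
    out.insert(0, "sample_id", table.sample_id)
    out["cq"] = [
        "NA" if not np.isfinite(v) else f"{v:.4f}" for v in out["cq"]
    ]
    out.to_csv(path, index=False)


def round_cq(table: CqTable) -> CqTable:
    """Round Cq values to the 4-decimal on-disk precision."""
    data = table.data.copy()
    data["cq"] = np.round(data["cq"].to_numpy(dtype=float), 4)
    return CqTable(table.sample_id, table.chip_id, data)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str,
                                  "class_label": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False)
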