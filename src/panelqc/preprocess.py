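"""Clinical preprocessing chain for plasma miRNA profiles.

Fixed stage order: hemolysis QC -> control normalization (ΔCq) ->
replicate averaging -> never-detected filtering -> per-profile max-ΔCq
imputation -> per-profile standardization.

The per-profile (row-wise) convention is deliberate: each profile's missing
values are replaced with that profile's maximum ΔCq (the least-abundant
observed signal — missingness in qPCR means "below the detection floor"),
and each profile is z-scored to zero mean and unit variance using the
population divisor. No cross-subject statistics enter these two stages,
so they leak nothing across cross-validation folds.

The matrix stages are exposed both as sklearn transformers
(:class:`NeverDetectedFilter`, :class:`MaxDeltaCqImputer`,
:class:`ProfileStandardizer`) that compose with sklearn pipelines, and as
thin functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .chipio import ChipLayout, Config, CqTable, SampleSheet
from .errors import (
    ChipDataError,
    ConsistencyError,
    DegenerateProfileError,
    NormalizationError,
)
from .qcmetrics import DetectionCall, call_detection, calls_by_assay


def hemolysis_check(a414: float, a375: float) -> str:
    """Plasma hemolysis rule: exclude when A414/A375 exceeds 2 (strictly)."""
    if a375 <= 0:
        raise ChipDataError("A375 must be positive")
    return "exclude" if a414 / a375 > 2.0 else "pass"


@dataclass
class ExpressionProfile:
    """Per-sample ΔCq values (lower = more abundant) with explicit missingness."""

    sample_id: str
    values: pd.Series  # index assay_id, NaN = missing
    normalization_mode: str = "none"


def normalize_profile(
    calls: list[DetectionCall],
    factors: list[str],
    sample_id: str = "sample",
    assay_universe: list[str] | None = None,
    mode: str = "process_controls",
) -> ExpressionProfile:
    """ΔCq normalization: subtract the mean Cq of the factor assays.

    Every factor must be detected in the sample; otherwise a
    :class:`NormalizationError` names the offending factor. Undetected
    target assays stay missing (NaN).
    """
    by = calls_by_assay(calls)
    factor_cqs = []
    for f in factors:
        c = by.get(f)
        if c is None or not c.detected:
            raise NormalizationError(
                f"normalization factor {f!r} not detected in sample {sample_id!r}"
            )
        factor_cqs.append(c.collapsed_cq)
    ref = float(np.mean(factor_cqs))
    universe = assay_universe if assay_universe is not None else [c.assay_id for c in calls]
    vals = pd.Series(
        {
            a: (by[a].collapsed_cq - ref if a in by and by[a].detected else np.nan)
            for a in universe
        },
        dtype=float,
    )
    return ExpressionProfile(sample_id=sample_id, values=vals, normalization_mode=mode)


def average_replicates(profiles: list[ExpressionProfile]) -> pd.Series:
    """Per-assay mean ΔCq over one subject's replicate profiles.

    Available-case analysis: the mean runs over non-missing replicates;
    an assay is missing only when it is missing in every replicate.
    """
    if not profiles:
        raise ChipDataError("empty replicate group")
    frame = pd.DataFrame({p.sample_id: p.values for p in profiles})
    return frame.mean(axis=1, skipna=True)


# ---------------------------------------------------------------------------
# Matrix-stage transformers (sklearn API)

class NeverDetectedFilter(BaseEstimator, TransformerMixin):
    """Drop assays (columns) missing in every profile of the cohort.

    Fitted attributes: ``retained_mask_`` (bool per input column) and, for
    DataFrame input, ``retained_columns_`` in the original column order.
    """

    def fit(self, X, y=None):
        values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if values.ndim != 2 or values.shape[0] == 0:
            raise ChipDataError("cohort matrix must be 2-D and non-empty")
        self.retained_mask_ = np.isfinite(values).any(axis=0)
        self.n_features_in_ = values.shape[1]
        if isinstance(X, pd.DataFrame):
            self.retained_columns_ = list(X.columns[self.retained_mask_])
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_mask_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, X.columns[self.retained_mask_]]
        return np.asarray(X, float)[:, self.retained_mask_]


class MaxDeltaCqImputer(BaseEstimator, TransformerMixin):
    """Replace each profile's missing values with that profile's maximum ΔCq.

    Row-wise and stateless: no statistic crosses profiles, so fit is a
    no-op and the transform cannot leak between CV folds.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = np.shape(X)[1]
        return self

    def transform(self, X):
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
            X = X.to_numpy(dtype=float)
        out = np.array(X, dtype=float, copy=True)
        for i in range(out.shape[0]):
            row = out[i]
            missing = ~np.isfinite(row)
            if missing.all():
                raise DegenerateProfileError(f"profile row {i} is entirely missing")
            if missing.any():
                row[missing] = np.max(row[~missing])
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


class ProfileStandardizer(BaseEstimator, TransformerMixin):
    """Row-wise z-score: each profile to zero mean, unit (population) variance."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.shape(X)[1]
        return self

    def transform(self, X):
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
            X = X.to_numpy(dtype=float)
        out = np.array(X, dtype=float, copy=True)
        mu = out.mean(axis=1, keepdims=True)
        sd = out.std(axis=1, keepdims=True)  # population divisor n
        if np.any(sd == 0):
            i = int(np.where(sd.ravel() == 0)[0][0])
            raise DegenerateProfileError(f"profile row {i} has zero variance")
        out = (out - mu) / sd
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


# thin functional wrappers over the transformers

def filter_features(cohort: pd.DataFrame) -> list:
    """Assay ids retained after dropping never-detected columns
    (layout/input order preserved)."""
    return NeverDetectedFilter().fit(cohort).retained_columns_


def impute_missing(row: pd.Series) -> pd.Series:
    """Complete one profile row with its own maximum ΔCq."""
    out = MaxDeltaCqImputer().fit_transform(row.to_frame().T.astype(float))
    return out.iloc[0]


def standardize_profile(row: pd.Series) -> pd.Series:
    """Z-score one profile row (population variance)."""
    out = ProfileStandardizer().fit_transform(row.to_frame().T.astype(float))
    return out.iloc[0]


# ---------------------------------------------------------------------------
# Cohort assembly

@dataclass
class CohortMatrix:
    """Subjects x assays ΔCq matrix after averaging, plus class labels."""

    values: pd.DataFrame          # index subject_id, columns assay_id
    labels: pd.Series             # index subject_id, values in {OSCC, HD}
    n_excluded_hemolysis: int = 0

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "subject_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CohortMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("label")
        return cls(values=df, labels=labels)


def build_cohort_matrix(
    tables: list[CqTable],
    sheet: SampleSheet,
    layout: ChipLayout,
    config: Config,
) -> CohortMatrix:
    """Full chain from raw chip runs to the analysis-ready cohort matrix.

    Hemolysis-failing samples are excluded before any modelling; profiles
    are normalized with the configured factor assays, averaged per subject,
    filtered, imputed, and standardized.
    """
    meta = sheet.data.set_index("sample_id")
    universe = layout.target_ids
    profiles_by_subject: dict[str, list[ExpressionProfile]] = {}
    labels: dict[str, str] = {}
    n_hemolyzed = 0
    for t in tables:
        if t.sample_id not in meta.index:
            raise ConsistencyError(f"sample {t.sample_id!r} missing from sample sheet")
        row = meta.loc[t.sample_id]
        if hemolysis_check(float(row["a414"]), float(row["a375"])) == "exclude":
            n_hemolyzed += 1
            continue
        calls = call_detection(t, layout, config)
        prof = normalize_profile(
            calls,
            list(config.normalization_factors),
            sample_id=t.sample_id,
            assay_universe=universe,
        )
        subj = str(row["subject_id"])
        profiles_by_subject.setdefault(subj, []).append(prof)
        labels[subj] = str(row["class_label"])

    if not profiles_by_subject:
        raise ChipDataError("no samples survive hemolysis QC")
    subjects = list(profiles_by_subject)
    averaged = pd.DataFrame(
        {s: average_replicates(profiles_by_subject[s]) for s in subjects}
    ).T
    averaged = averaged.loc[:, universe]

    retained = filter_features(averaged)
    filtered = averaged.loc[:, retained]
    completed = MaxDeltaCqImputer().fit_transform(filtered)
    standardized = ProfileStandardizer().fit_transform(completed)
    return CohortMatrix(
        values=standardized,
        labels=pd.Series({s: labels[s] for s in subjects}),
        n_excluded_hemolysis=n_hemolyzed,
    )
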