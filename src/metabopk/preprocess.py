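"""Untargeted-metabolomics matrix preprocessing.

Stage order (fixed): QC-anchored drift correction -> half-minimum zero
replacement -> IQR near-constant filter -> QC-RSD reproducibility
filter -> log10 + Pareto scaling.  The drift correction estimates each
feature's intensity trend over injection order from the pooled-QC
injections with a local-regression (LOWESS) smoother and divides it
out, rescaling to the feature's QC median; features with too few
positive QC values fall back to a global median-ratio normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import FeatureMatrix

__all__ = [
    "PreprocessReport",
    "qc_rsd",
    "correct_drift",
    "impute_half_min",
    "filter_iqr",
    "filter_qc_rsd",
    "transform_log_pareto",
    "run_preprocessing",
]


@dataclass
class PreprocessReport:
    """Bookkeeping for the filtering cascade."""

    n_features_in: int = 0
    n_removed_iqr: int = 0
    n_removed_rsd: int = 0
    n_zeros_replaced: int = 0
    removed_iqr_ids: list[str] = field(default_factory=list)
    removed_rsd_ids: list[str] = field(default_factory=list)
    qc_rsd_before: pd.Series | None = None
    qc_rsd_after: pd.Series | None = None

    @property
    def n_features_out(self) -> int:
        return self.n_features_in - self.n_removed_iqr - self.n_removed_rsd

    def to_json_dict(self) -> dict:
        return {
            "n_features_in": self.n_features_in,
            "n_removed_iqr": self.n_removed_iqr,
            "n_removed_rsd": self.n_removed_rsd,
            "n_features_out": self.n_features_out,
            "n_zeros_replaced": self.n_zeros_replaced,
            "removed_iqr_ids": self.removed_iqr_ids,
            "removed_rsd_ids": self.removed_rsd_ids,
        }


def qc_rsd(matrix: FeatureMatrix) -> pd.Series:
    """Per-feature relative standard deviation over QC injections (%).

    Features whose QC mean is 0 get infinite RSD (nothing reproducible
    was measured).
    """
    qc = matrix.qc_intensities()
    if len(qc) < 2:
        raise ValueError("need at least 2 QC samples for RSD")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    return rsd.where(mean > 0, np.inf)


def correct_drift(matrix: FeatureMatrix, span: float = 0.75) -> FeatureMatrix:
    """Divide out the QC-estimated signal drift over injection order.

    Per feature, a LOWESS curve of QC intensity against injection order
    (fraction ``span``) is interpolated to every injection; intensities
    are divided by the curve and rescaled to the feature's QC median.
    Features with fewer than 3 positive QC values instead get a global
    median-ratio normalization (per-injection size factor from all
    features with positive QC medians).  Zeros stay zero.
    """
    qc_mask = matrix.is_qc.to_numpy()
    if qc_mask.sum() < 3:
        raise ValueError("drift correction needs at least 3 QC samples")
    order = matrix.sample_meta["injection_order"].to_numpy(dtype=float)
    qc_order = order[qc_mask]
    values = matrix.intensities.to_numpy(dtype=float).copy()
    qc_values = values[qc_mask]

    corrected = values.copy()
    fallback_cols: list[int] = []
    for j in range(values.shape[1]):
        qv = qc_values[:, j]
        pos = qv > 0
        if pos.sum() < 3:
            fallback_cols.append(j)
            continue
        fit = lowess(qv[pos], qc_order[pos], frac=span, return_sorted=True)
        curve = np.interp(order, fit[:, 0], fit[:, 1])
        if np.any(curve <= 0):
            fallback_cols.append(j)
            continue
        qc_median = np.median(qv[pos])
        corrected[:, j] = values[:, j] / curve * qc_median

    if fallback_cols:
        # size factor per injection: median intensity ratio to the QC-median
        # reference over well-measured features
        ref_cols = [j for j in range(values.shape[1]) if j not in set(fallback_cols)]
        if ref_cols:
            ref = np.median(qc_values[:, ref_cols], axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = values[:, ref_cols] / ref
            ratios = np.where(values[:, ref_cols] > 0, ratios, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                factors = np.nanmedian(ratios, axis=1)
            factors = np.where(np.isfinite(factors) & (factors > 0), factors, 1.0)
        else:
            factors = np.ones(values.shape[0])
        for j in fallback_cols:
            corrected[:, j] = values[:, j] / factors

    corrected[values == 0] = 0.0
    out = pd.DataFrame(corrected, index=matrix.intensities.index, columns=matrix.feature_ids)
    return matrix.replace_intensities(out)


def impute_half_min(matrix: FeatureMatrix, per_feature: bool = False) -> FeatureMatrix:
    """Replace zeros by half of the smallest positive value.

    The minimum is global over the whole matrix by default (the
    ``per_feature`` flag switches to column-wise minima).  Idempotent:
    a matrix without zeros is returned unchanged.
    """
    values = matrix.intensities.to_numpy(dtype=float).copy()
    if not (values > 0).any():
        raise ValueError("all-zero matrix: nothing to anchor the imputation")
    zeros = values == 0
    if not zeros.any():
        return matrix
    if per_feature:
        for j in range(values.shape[1]):
            col = values[:, j]
            pos = col[col > 0]
            fill = pos.min() / 2 if pos.size else np.min(values[values > 0]) / 2
            col[col == 0] = fill
    else:
        fill = values[values > 0].min() / 2.0
        values[zeros] = fill
    out = pd.DataFrame(values, index=matrix.intensities.index, columns=matrix.feature_ids)
    return matrix.replace_intensities(out)


def filter_iqr(
    matrix: FeatureMatrix, drop_fraction: float = 0.10
) -> tuple[FeatureMatrix, list[str]]:
    """Drop the lowest ``drop_fraction`` of features by interquartile range.

    The IQR is computed over biological (non-QC) samples; exactly
    floor(drop_fraction * n_features) features are removed, ties broken
    by feature id order (earlier columns removed first).
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    n = matrix.intensities.shape[1]
    n_drop = int(np.floor(drop_fraction * n))
    if n_drop == 0:
        return matrix, []
    bio = matrix.biological_intensities()
    iqr = bio.quantile(0.75) - bio.quantile(0.25)
    # stable sort keeps column order among ties
    ranked = iqr.iloc[np.argsort(iqr.to_numpy(), kind="stable")]
    removed = list(ranked.index[:n_drop])
    kept = [f for f in matrix.feature_ids if f not in set(removed)]
    return matrix.subset_features(kept), removed


def filter_qc_rsd(
    matrix: FeatureMatrix, threshold: float = 20.0
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features whose QC RSD exceeds ``threshold`` percent."""
    rsd = qc_rsd(matrix)
    removed = list(rsd.index[rsd > threshold])
    kept = [f for f in matrix.feature_ids if f not in set(removed)]
    return matrix.subset_features(kept), removed


def transform_log_pareto(matrix: FeatureMatrix) -> FeatureMatrix:
    """log10 transform then Pareto scale (center, divide by sqrt(SD)).

    Requires a strictly positive matrix (run imputation first).  A
    feature with zero variance after the log is centered but not
    divided, with a warning.
    """
    values = matrix.intensities.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("log transform requires strictly positive intensities")
    logged = np.log10(values)
    sd = logged.std(axis=0, ddof=1)
    centered = logged - logged.mean(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s) centered but not scaled"
        )
    divisor = np.where(zero_var, 1.0, np.sqrt(sd))
    out = pd.DataFrame(
        centered / divisor, index=matrix.intensities.index, columns=matrix.feature_ids
    )
    return matrix.replace_intensities(out, is_scaled=True)


def run_preprocessing(
    matrix: FeatureMatrix,
    span: float = 0.75,
    iqr_drop_fraction: float = 0.10,
    rsd_threshold: float = 20.0,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Full cascade in the fixed stage order, with bookkeeping."""
    report = PreprocessReport(n_features_in=matrix.intensities.shape[1])
    report.qc_rsd_before = qc_rsd(matrix)
    corrected = correct_drift(matrix, span=span)
    report.qc_rsd_after = qc_rsd(corrected)
    report.n_zeros_replaced = int((corrected.intensities.to_numpy() == 0).sum())
    imputed = impute_half_min(corrected)
    filtered, removed_iqr = filter_iqr(imputed, drop_fraction=iqr_drop_fraction)
    report.removed_iqr_ids = removed_iqr
    report.n_removed_iqr = len(removed_iqr)
    filtered, removed_rsd = filter_qc_rsd(filtered, threshold=rsd_threshold)
    report.removed_rsd_ids = removed_rsd
    report.n_removed_rsd = len(removed_rsd)
    scaled = transform_log_pareto(filtered)
    return scaled, report
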