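"""Pre- vs post-dose differential abundance with empirical-Bayes moderation.

Subject blocking is realized by paired differencing: the per-feature
response is each subject's post-minus-pre scaled abundance, modeled by
ordinary least squares on an intercept (the dose effect) plus sex,
centered age, centered BMI and crossover period.  Residual variances
are shrunk toward a common prior whose degrees of freedom d0 and scale
s0^2 are estimated by matching the moments of log s_g^2 through
digamma/trigamma inversion; the moderated t uses d0 + d_g degrees of
freedom.  Multiplicity is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureMatrix, SubjectProfile

__all__ = [
    "EBHyperparams",
    "build_design",
    "fit_feature_models",
    "moderate_variances",
    "adjust_bh",
    "select_features",
    "run_differential",
]


@dataclass
class EBHyperparams:
    """Prior degrees of freedom and scale of the variance prior."""

    d0: float  # may be inf: complete shrinkage to s0_sq
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be nonnegative (inf allowed)")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def build_design(
    sample_meta: pd.DataFrame,
    subjects: list[SubjectProfile],
    covariates: bool = True,
) -> pd.DataFrame:
    """Design matrix of the paired (post - pre) model, one row per subject.

    Columns: intercept (the dose effect), sex (M = 1), centered age,
    centered BMI, period (period 2 = 1).  Constant covariate columns
    (e.g. an all-female cohort) are dropped with a warning since they
    make the design rank deficient.  With ``covariates=False`` the model
    reduces to the intercept-only paired t-test setup.
    """
    bio = sample_meta[sample_meta["phase"] != "qc"]
    counts = bio.groupby("subject_id")["phase"].agg(lambda s: sorted(s))
    for sid, phases in counts.items():
        if phases != ["post", "pre"]:
            raise ValueError(f"subject {sid!r} is not paired (phases: {phases})")
    by_id = {s.subject_id: s for s in subjects}
    missing = [sid for sid in counts.index if sid not in by_id]
    if missing:
        raise ValueError(f"no subject profile for {missing}")
    order = sorted(counts.index)
    design = pd.DataFrame(index=pd.Index(order, name="subject_id"))
    design["intercept"] = 1.0
    if covariates:
        design["sex"] = [1.0 if by_id[sid].sex == "M" else 0.0 for sid in order]
        age = np.array([by_id[sid].age for sid in order])
        bmi = np.array([by_id[sid].bmi for sid in order])
        design["age"] = age - age.mean()
        design["bmi"] = bmi - bmi.mean()
        design["period"] = [1.0 if by_id[sid].period == 2 else 0.0 for sid in order]
        for col in ("sex", "period"):
            if design[col].nunique() == 1:
                warnings.warn(f"covariate {col!r} is constant; dropped")
                design = design.drop(columns=col)
    return design


def paired_differences(matrix: FeatureMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre response matrix aligned to the design's subjects."""
    post = matrix.phase_abundance("post").loc[design.index]
    pre = matrix.phase_abundance("pre").loc[design.index]
    return post - pre


def fit_feature_models(
    responses: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature OLS of the paired differences on the design.

    Returns a feature-indexed frame with the dose effect (intercept
    coefficient), residual variance s2_g and residual degrees of
    freedom df_g.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom (n <= p)")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    Y = responses.to_numpy(dtype=float)  # n x G
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    out = pd.DataFrame(
        {
            "effect": beta[0],
            "s2_g": s2,
            "df_g": float(df),
            "unscaled_var": xtx_inv[0, 0],
        },
        index=responses.columns,
    )
    out.index.name = "feature_id"
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(
    fits: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> tuple[EBHyperparams, pd.DataFrame]:
    """Empirical-Bayes variance shrinkage and moderated t-statistics.

    Hyperparameters are estimated from the marginal distribution of
    log s_g^2: with z_g = log s_g^2 and e_g = z_g - digamma(d_g/2) +
    log(d_g/2), matching moments gives trigamma(d0/2) = var(e) -
    mean(trigamma(d_g/2)) (d0 = inf when the right side is <= 0) and
    s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2)).  The posterior
    variance is the convex combination (d0 s0^2 + d_g s_g^2)/(d0 + d_g);
    t_mod = effect / sqrt(s2_post * v) on d0 + d_g degrees of freedom.
    Forcing ``d0=0`` reproduces the ordinary t exactly; ``d0=inf``
    shrinks every variance to s0^2.
    """
    s2 = fits["s2_g"].to_numpy(dtype=float)
    df = fits["df_g"].to_numpy(dtype=float)
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero; nothing to moderate")
    if d0 is None or s0_sq is None:
        if len(fits) < 10:
            raise ValueError("need >= 10 features to estimate hyperparameters")
        ok = s2 > 0
        z = np.log(s2[ok])
        e = z - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
        e_mean = e.mean()
        rhs = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2))
        if d0 is None:
            d0 = 2.0 * _trigamma_inverse(rhs) if rhs > 0 else np.inf
        if s0_sq is None:
            if np.isfinite(d0) and d0 > 0:
                s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
            else:
                # with no detectable spread beyond sampling noise the
                # per-feature s2 are unbiased for the common variance
                s0_sq = float(np.mean(s2[ok]))
    hyper = EBHyperparams(d0=float(d0), s0_sq=float(s0_sq))

    if hyper.d0 == 0:
        s2_post = s2.copy()
        df_total = df
    elif np.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + df * s2) / (hyper.d0 + df)
        df_total = hyper.d0 + df
    v = fits["unscaled_var"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits["effect"].to_numpy(dtype=float) / np.sqrt(s2_post * v)
    # total df capped at the pooled residual df (finite-sample guard)
    df_for_p = np.minimum(df_total, df.sum())
    p_raw = 2 * stats.t.sf(np.abs(t_mod), df_for_p)
    out = fits.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p_raw"] = p_raw
    return hyper, out


def adjust_bh(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_features(results: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Feature ids with BH q-value at or below ``alpha``."""
    return list(results.index[results["q_bh"] <= alpha])


def run_differential(
    matrix: FeatureMatrix,
    subjects: list[SubjectProfile],
    alpha: float = 0.05,
    covariates: bool = True,
) -> pd.DataFrame:
    """Full selection on one (scaled) matrix: design, OLS, moderation, BH."""
    design = build_design(matrix.sample_meta, subjects, covariates=covariates)
    responses = paired_differences(matrix, design)
    fits = fit_feature_models(responses, design)
    _, results = moderate_variances(fits)
    results["q_bh"] = adjust_bh(results["p_raw"])
    results["selected"] = results["q_bh"] <= alpha
    return results
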