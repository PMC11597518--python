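"""Non-compartmental pharmacokinetic analysis of single-dose profiles.

Per subject: Cmax and Tmax read directly off the observed curve, AUC0-t
by the linear trapezoidal rule up to the last positive concentration,
and the terminal elimination constant Kel from an ordinary
least-squares fit of ln(concentration) against time over the
best-adjusted-R^2 suffix window of 3-8 post-Tmax points.  T1/2 is
ln(2)/Kel.  The study-level summary reports mean, minimum, median,
maximum, sample standard deviation and CV% per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConcProfile

__all__ = [
    "NCAError",
    "PKParameters",
    "compute_cmax_tmax",
    "compute_auc_0_t",
    "fit_terminal_slope",
    "half_life",
    "analyze_profile",
    "analyze_study",
    "cv_percent",
    "summarize_parameters",
    "SUMMARY_ROW_ORDER",
]

#: parameter row order of the descriptive-statistics table
SUMMARY_ROW_ORDER = ("Cmax", "AUC0-t", "T1/2", "Tmax", "Kel")


class NCAError(ValueError):
    """A profile violates an NCA precondition (no absorption, bad tail...)."""


@dataclass
class PKParameters:
    subject_id: str
    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_t: float  # h*ng/mL
    kel: float  # 1/h
    t_half: float  # h
    terminal_points_used: int
    terminal_fit_r2adj: float


def compute_cmax_tmax(profile: ConcProfile) -> tuple[float, float]:
    """Maximum observed concentration and the earliest time achieving it."""
    if len(profile) < 2:
        raise NCAError("need at least 2 observations")
    conc = profile.concentrations
    if np.all(conc == 0):
        raise NCAError(f"{profile.subject_id}: all-zero profile (no absorption)")
    i = int(np.argmax(conc))  # argmax returns the first maximum: tie -> earliest
    return float(conc[i]), float(profile.times[i])


def compute_auc_0_t(profile: ConcProfile) -> float:
    """Linear trapezoidal AUC from dose to the last positive concentration."""
    if len(profile) < 2:
        raise NCAError("need at least 2 observations")
    t, c = profile.times, profile.concentrations
    positive = np.nonzero(c > 0)[0]
    if positive.size == 0:
        raise NCAError("no positive concentrations")
    last = positive[-1]
    return float(np.trapezoid(c[: last + 1], t[: last + 1]))


def fit_terminal_slope(
    profile: ConcProfile, min_points: int = 3, max_points: int = 8
) -> tuple[float, int, float]:
    """Terminal log-linear regression with adjusted-R^2 window selection.

    Candidate windows are the suffixes of k in {min_points..max_points}
    positive-concentration points strictly after Tmax; the window
    maximizing adjusted R^2 wins, ties going to more points.  Returns
    (kel, points_used, r2adj); a window only qualifies if its slope is
    negative (kel > 0).
    """
    _, tmax = compute_cmax_tmax(profile)
    mask = (profile.times > tmax) & (profile.concentrations > 0)
    t = profile.times[mask]
    c = profile.concentrations[mask]
    if t.size < min_points:
        raise NCAError(
            f"{profile.subject_id}: fewer than {min_points} positive post-Tmax points"
        )
    y = np.log(c)
    best: tuple[float, int, float] | None = None  # (r2adj, k, kel)
    for k in range(min_points, min(max_points, t.size) + 1):
        res = stats.linregress(t[-k:], y[-k:])
        kel = -res.slope
        if kel <= 0:
            continue
        r2 = res.rvalue**2
        r2adj = 1 - (1 - r2) * (k - 1) / (k - 2)
        if best is None or r2adj > best[0] + 1e-12 or (abs(r2adj - best[0]) <= 1e-12 and k > best[1]):
            best = (r2adj, k, kel)
    if best is None:
        raise NCAError(f"{profile.subject_id}: no terminal window with positive Kel")
    r2adj, k, kel = best
    return float(kel), int(k), float(r2adj)


def half_life(kel: float) -> float:
    """Terminal half-life, t1/2 = ln(2)/Kel."""
    if kel <= 0:
        raise NCAError("kel must be positive")
    return math.log(2) / kel


def analyze_profile(profile: ConcProfile) -> PKParameters:
    cmax, tmax = compute_cmax_tmax(profile)
    auc = compute_auc_0_t(profile)
    kel, used, r2adj = fit_terminal_slope(profile)
    return PKParameters(
        subject_id=profile.subject_id,
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc,
        kel=kel,
        t_half=half_life(kel),
        terminal_points_used=used,
        terminal_fit_r2adj=r2adj,
    )


def analyze_study(profiles: list[ConcProfile]) -> pd.DataFrame:
    """Per-subject PK parameter table (columns named as association targets)."""
    rows = []
    for profile in profiles:
        p = analyze_profile(profile)
        rows.append(
            {
                "subject_id": p.subject_id,
                "Cmax": p.cmax,
                "Tmax": p.tmax,
                "AUC0-t": p.auc_0_t,
                "Kel": p.kel,
                "T1/2": p.t_half,
                "terminal_points_used": p.terminal_points_used,
                "terminal_fit_r2adj": p.terminal_fit_r2adj,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * sd / mean."""
    if mean == 0:
        raise ValueError("CV%% undefined for zero mean")
    return 100.0 * sd / mean


def summarize_parameters(pk_table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per PK parameter.

    Sample SD uses n-1; the median of an even-length sample is the
    midpoint average.  Rows follow the conventional reporting order.
    """
    if len(pk_table) < 2:
        raise ValueError("need at least 2 subjects to summarize")
    rows = {}
    for name in SUMMARY_ROW_ORDER:
        v = pk_table[name].to_numpy(dtype=float)
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
        rows[name] = {
            "mean": mean,
            "minimum": float(np.min(v)),
            "median": float(np.median(v)),
            "maximum": float(np.max(v)),
            "sd": sd,
            "cv_percent": cv_percent(mean, sd) if mean != 0 else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "parameter"
    return out
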