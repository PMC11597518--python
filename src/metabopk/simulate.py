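"""Synthetic single-dose pharmacometabolomics study generator.

Emulates the data shapes of a 35-volunteer single-oral-dose study:
one-compartment absorption/elimination kinetics per subject, an
untargeted feature-intensity matrix sampled pre-dose and at the drug
peak (post-dose) with pooled-QC injections and multiplicative
injection-order drift, a clinical/laboratory characteristics table, and
a pathway-annotation fixture.  Every planted effect (differential
features, metabolite-target dependencies of chosen distance-correlation
strength) is recorded as ground truth so downstream recovery can be
measured.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationPlant,
    ConcProfile,
    DegenerateModelError,
    FeatureMatrix,
    PathwayFixture,
    PathwayRecord,
    PKModelParams,
    PlantedTruth,
    SubjectProfile,
)
from .network import distance_correlation

__all__ = [
    "DEFAULT_TIME_GRID",
    "DEFAULT_CHARACTERISTICS",
    "TARGET_CLASSES",
    "PK_PARAMETER_NAMES",
    "tmax_closed_form",
    "cmax_closed_form",
    "simulate_concentration",
    "realize_subject_params",
    "simulate_cohort",
    "simulate_feature_matrix",
    "generate_pathway_fixture",
    "characteristics_table",
]

#: default sampling schedule (hours post dose)
DEFAULT_TIME_GRID = np.array(
    [0.0, 0.5, 1, 2, 3, 4, 5, 6, 7, 7.5, 8, 10, 12, 24, 36, 48, 72.0]
)

#: characteristic name -> (mean, sd) of the healthy-volunteer sampling normal
DEFAULT_CHARACTERISTICS: dict[str, tuple[float, float]] = {
    "Systolic pressure": (117.0, 9.0),  # mmHg
    "Diastolic pressure": (74.0, 7.0),  # mmHg
    "Heart rate": (68.0, 8.0),  # bpm
    "AST": (24.0, 6.0),  # U/L
    "Serum total cholesterol": (178.0, 28.0),  # mg/dL
    "Serum creatinine": (0.88, 0.14),  # mg/dL
    "Uric acid": (5.1, 1.1),  # mg/dL
    "Hemoglobin": (14.6, 1.1),  # g/dL
    "Hematocrit": (43.5, 3.2),  # %
    "RDW": (13.4, 0.8),  # %
    "Fasting glucose": (89.0, 7.0),  # mg/dL
    "Total bilirubin": (0.7, 0.22),  # mg/dL
    "Alkaline phosphatase": (71.0, 16.0),  # U/L
    "Leukocytes": (6.4, 1.4),  # 10^3/uL
    "Leukocytes in urine": (2.1, 1.0),  # cells/field
}

PK_PARAMETER_NAMES = ("Cmax", "Tmax", "AUC0-t", "Kel", "T1/2")

#: node class of every association target the generator knows about
TARGET_CLASSES: dict[str, str] = {name: "pk_parameter" for name in PK_PARAMETER_NAMES}
TARGET_CLASSES.update(
    {
        "Systolic pressure": "clinical",
        "Diastolic pressure": "clinical",
        "Heart rate": "clinical",
        "Leukocytes in urine": "laboratory_urine",
    }
)
for _name in DEFAULT_CHARACTERISTICS:
    TARGET_CLASSES.setdefault(_name, "laboratory_serum")


def tmax_closed_form(ka: float, ke: float) -> float:
    """Analytic time of peak concentration: ln(ka/ke) / (ka - ke)."""
    if ka <= 0 or ke <= 0:
        raise ValueError("rate constants must be positive")
    if ka == ke:
        raise DegenerateModelError("ka == ke has no closed-form Tmax")
    return math.log(ka / ke) / (ka - ke)


def cmax_closed_form(params: PKModelParams) -> float:
    """Peak concentration of the noiseless one-compartment profile."""
    tmax = tmax_closed_form(params.ka, params.ke)
    return float(_model_concentration(params, np.array([tmax]))[0])


def _model_concentration(params: PKModelParams, times: np.ndarray) -> np.ndarray:
    d, ka, ke, v = params.dose, params.ka, params.ke, params.v_over_f
    return (d / v) * (ka / (ka - ke)) * (np.exp(-ke * times) - np.exp(-ka * times))


def simulate_concentration(
    params: PKModelParams,
    times: Sequence[float] | None = None,
    subject_id: str = "S01",
    rng: np.random.Generator | None = None,
) -> ConcProfile:
    """Evaluate the one-compartment oral model on a sampling grid.

    C(t) = (D / (V/F)) * ka/(ka-ke) * (exp(-ke t) - exp(-ka t)).
    Proportional (log-normal) assay noise of CV ``params.residual_cv``
    is applied when a random generator is supplied; t=0 stays exactly 0.
    """
    if params.ka == params.ke:
        raise DegenerateModelError("ka == ke: perturb one rate before simulating")
    t = np.asarray(DEFAULT_TIME_GRID if times is None else times, dtype=float)
    if t[0] != 0:
        raise ValueError("sampling times must start at 0")
    conc = _model_concentration(params, t)
    conc = np.clip(conc, 0.0, None)
    if rng is not None and params.residual_cv > 0:
        sigma = math.sqrt(math.log(1 + params.residual_cv**2))
        conc = conc * np.exp(rng.normal(0.0, sigma, size=conc.size))
        conc[t == 0] = 0.0
    return ConcProfile(subject_id=subject_id, times=t, concentrations=conc)


def realize_subject_params(
    base: PKModelParams, rng: np.random.Generator
) -> PKModelParams:
    """Draw one subject's parameters with log-normal inter-individual variability."""

    def _draw(value: float, cv: float) -> float:
        if cv <= 0:
            return value
        sigma = math.sqrt(math.log(1 + cv**2))
        return value * math.exp(rng.normal(-0.5 * sigma**2, sigma))

    ka = _draw(base.ka, base.iiv_cv_ka)
    ke = _draw(base.ke, base.iiv_cv_ke)
    v = _draw(base.v_over_f, base.iiv_cv_v)
    if abs(ka - ke) < 1e-9 * max(ka, ke):
        ka *= 1.01  # degenerate collision: perturb absorption
    return PKModelParams(
        dose=base.dose,
        ka=ka,
        ke=ke,
        v_over_f=v,
        iiv_cv_ka=base.iiv_cv_ka,
        iiv_cv_ke=base.iiv_cv_ke,
        iiv_cv_v=base.iiv_cv_v,
        residual_cv=base.residual_cv,
    )


def simulate_cohort(
    n_subjects: int,
    seed: int,
    characteristics: Mapping[str, tuple[float, float]] | None = None,
) -> list[SubjectProfile]:
    """Generate a balanced healthy-volunteer cohort.

    Sexes and crossover periods are balanced (within one subject for odd
    n), ages uniform on 18-50 years, BMI uniform on 18.5-30 kg/m^2, and
    clinical/laboratory characteristics drawn from configurable normals
    truncated at zero.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    chars = dict(DEFAULT_CHARACTERISTICS if characteristics is None else characteristics)
    rng = np.random.default_rng(seed)
    sexes = np.array(["F", "M"])[np.arange(n_subjects) % 2]
    periods = (np.arange(n_subjects) % 2) + 1
    rng.shuffle(sexes)
    rng.shuffle(periods)
    profiles = []
    for i in range(n_subjects):
        values = {
            name: float(np.clip(rng.normal(mu, sd), 0.05 * mu if mu > 0 else 0.0, None))
            for name, (mu, sd) in chars.items()
        }
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                sex=str(sexes[i]),
                age=float(np.round(rng.uniform(18, 50), 1)),
                bmi=float(np.round(rng.uniform(18.5, 30.0), 1)),
                period=int(periods[i]),
                characteristics=values,
            )
        )
    return profiles


def characteristics_table(subjects: Sequence[SubjectProfile]) -> pd.DataFrame:
    """Subject-indexed table of demographics plus characteristic values."""
    rows = {}
    for s in subjects:
        row = {"sex": s.sex, "age": s.age, "bmi": s.bmi, "period": s.period}
        row.update(s.characteristics)
        rows[s.subject_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out.sort_index()


def _drift_curve(u: np.ndarray, end_multiplier: float, shape: float = 1.0) -> np.ndarray:
    """Monotone exponential-plus-linear drift from 1 to ``end_multiplier``.

    ``u`` is the normalized injection position in [0, 1]; the curve is a
    50/50 blend of a linear ramp and a saturating exponential, which is
    smooth, monotone, and correctable by a local-regression smoother.
    """
    ramp = 0.5 * u + 0.5 * (np.expm1(shape * u) / np.expm1(shape))
    return 1.0 + (end_multiplier - 1.0) * ramp


def _calibrate_association(
    target: np.ndarray,
    sign: int,
    target_dcor: float,
    latent_noise: np.ndarray,
    resid: np.ndarray,
    sigma_subject: float,
    tol: float = 0.005,
) -> tuple[np.ndarray, float]:
    """Bisect the coupling weight so the realized sample dCor hits target.

    The subject-level latent is v = g*z + sqrt(1-g^2)*e with z the
    standardized (signed) target; the realized distance correlation of
    sigma*v + resid against the raw target is monotone in g, so 50
    bisection steps land well inside the +-0.1 contract.
    """
    z = (target - target.mean()) / target.std(ddof=0)
    z = sign * z

    def realized(g: float) -> float:
        v = g * z + math.sqrt(max(1.0 - g * g, 0.0)) * latent_noise
        return distance_correlation(sigma_subject * v + resid, target)

    lo, hi = 0.0, 1.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_dcor:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    g = 0.5 * (lo + hi)
    v = g * z + math.sqrt(max(1.0 - g * g, 0.0)) * latent_noise
    return sigma_subject * v, g


def simulate_feature_matrix(
    subjects: Sequence[SubjectProfile],
    n_features: int = 500,
    n_differential: int = 50,
    association_spec: Sequence[tuple[str, str, float, int]] = (),
    qc_every: int = 10,
    seed: int = 0,
    *,
    targets: pd.DataFrame | None = None,
    lfc_magnitude: float = 1.0,
    sigma_subject: float = 0.30,
    sigma_resid: float = 0.20,
    drift_fraction: float = 0.5,
    drift_amplitude: tuple[float, float] = (0.8, 1.25),
    zero_fraction: float = 0.005,
    qc_noise_sd: float = 0.05,
    ion_mode: str = "negative",
) -> tuple[FeatureMatrix, PlantedTruth]:
    """Generate the pre/post feature-intensity matrix with pooled QCs.

    Baseline log-intensities per feature are Normal(mu_f, sigma) on the
    natural-log scale with a shared subject random effect; post-dose
    samples of the ``n_differential`` planted features are shifted by a
    log-fold-change of magnitude >= ``lfc_magnitude`` with random sign.
    A monotone multiplicative drift in injection order (end multiplier
    uniform on ``drift_amplitude``) hits a random ``drift_fraction`` of
    features; pooled-QC injections (feature-wise mean of the biological
    samples, plus drift and small noise) are inserted after every
    ``qc_every`` biological injections.  Each ``association_spec`` entry
    (feature_id, target_name, target_dcor, sign) couples a feature to a
    PK parameter (via ``targets``) or subject characteristic through a
    shared latent variable calibrated by bisection so the realized
    sample distance correlation lands within +-0.1 of the request.
    """
    if n_differential > n_features:
        raise ValueError("n_differential cannot exceed n_features")
    rng = np.random.default_rng(seed)
    n_sub = len(subjects)
    subject_ids = [s.subject_id for s in subjects]
    feature_ids = [f"F{i + 1:04d}" for i in range(n_features)]

    mu = rng.normal(12.0, 1.5, size=n_features)
    b = rng.normal(0.0, sigma_subject, size=(n_sub, n_features))
    eps_pre = rng.normal(0.0, sigma_resid, size=(n_sub, n_features))
    eps_post = rng.normal(0.0, sigma_resid, size=(n_sub, n_features))

    # association-coupled features count toward the differential set so
    # they flow through downstream selection into the network stage, as
    # identified differential metabolites do in the real design
    fid_to_col = {fid: j for j, fid in enumerate(feature_ids)}
    assoc_cols: list[int] = []
    for fid, _, _, _ in association_spec:
        if fid not in fid_to_col:
            raise ValueError(f"association references unknown feature {fid!r}")
        if fid_to_col[fid] not in assoc_cols:
            assoc_cols.append(fid_to_col[fid])
    forced = assoc_cols[:n_differential]
    pool = np.setdiff1d(np.arange(n_features), np.array(forced, dtype=int))
    extra = rng.choice(pool, size=n_differential - len(forced), replace=False)
    diff_idx = np.concatenate([np.array(forced, dtype=int), extra]).astype(int)
    lfc = np.zeros(n_features)
    magnitudes = lfc_magnitude * rng.uniform(1.0, 1.5, size=n_differential)
    signs = rng.choice([-1.0, 1.0], size=n_differential)
    lfc[diff_idx] = magnitudes * signs

    # --- planted metabolite-target dependencies -------------------------
    char_table = characteristics_table(subjects)
    plants: list[AssociationPlant] = []
    for fid, target_name, target_dcor, sign in association_spec:
        if targets is not None and target_name in targets.columns:
            y = targets.loc[subject_ids, target_name].to_numpy(dtype=float)
        elif target_name in char_table.columns:
            y = char_table.loc[subject_ids, target_name].to_numpy(dtype=float)
        else:
            raise ValueError(
                f"association target {target_name!r} is neither a supplied PK "
                "parameter nor a subject characteristic"
            )
        j = fid_to_col[fid]
        # coupled features model identified metabolites: well above the
        # detection limit, so censoring cannot erase the dependence
        mu[j] = max(mu[j], 12.5)
        latent_noise = rng.normal(0.0, 1.0, size=n_sub)
        # small residuals on coupled features so the dependence survives
        resid_pre = rng.normal(0.0, 0.05, size=n_sub)
        resid_post = rng.normal(0.0, 0.05, size=n_sub)
        effect, _ = _calibrate_association(
            y, int(sign), float(target_dcor), latent_noise, resid_post, sigma_subject
        )
        b[:, j] = effect
        eps_pre[:, j] = resid_pre
        eps_post[:, j] = resid_post
        plants.append(
            AssociationPlant(
                feature_id=fid,
                target_name=target_name,
                target_dcor=float(target_dcor),
                sign=int(sign),
                realized_dcor_pre=distance_correlation(effect + resid_pre, y),
                realized_dcor_post=distance_correlation(effect + resid_post, y),
            )
        )

    log_pre = mu + b + eps_pre
    log_post = mu + b + lfc + eps_post

    # --- injection sequence: randomized biologicals, QC after each block -
    bio_ids = [f"{sid}_pre" for sid in subject_ids] + [f"{sid}_post" for sid in subject_ids]
    bio_meta = pd.DataFrame(
        {
            "subject_id": subject_ids * 2,
            "phase": ["pre"] * n_sub + ["post"] * n_sub,
        },
        index=pd.Index(bio_ids, name="sample_id"),
    )
    bio_raw = np.exp(np.vstack([log_pre, log_post]))
    order = rng.permutation(len(bio_ids))
    bio_ids = [bio_ids[i] for i in order]
    bio_raw = bio_raw[order]
    bio_meta = bio_meta.loc[bio_ids]

    pooled = bio_raw.mean(axis=0)
    n_qc = len(bio_ids) // qc_every
    rows, meta_rows = [], []
    injection = 0
    qc_count = 0
    for i, sid in enumerate(bio_ids):
        injection += 1
        rows.append((sid, bio_meta.loc[sid, "subject_id"], bio_meta.loc[sid, "phase"], injection, bio_raw[i]))
        if (i + 1) % qc_every == 0 and qc_count < n_qc:
            injection += 1
            qc_count += 1
            qc_vals = pooled * np.exp(rng.normal(0.0, qc_noise_sd, size=n_features))
            rows.append((f"QC{qc_count:02d}", "", "qc", injection, qc_vals))

    sample_ids = [r[0] for r in rows]
    raw = np.vstack([r[4] for r in rows])
    meta = pd.DataFrame(
        {
            "subject_id": [r[1] for r in rows],
            "phase": [r[2] for r in rows],
            "injection_order": [r[3] for r in rows],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- multiplicative injection-order drift ---------------------------
    n_drift = int(round(drift_fraction * n_features))
    drift_idx = rng.choice(n_features, size=n_drift, replace=False)
    n_inj = raw.shape[0]
    u = (meta["injection_order"].to_numpy(dtype=float) - 1) / max(n_inj - 1, 1)
    drift_profile: dict[str, dict[str, float]] = {}
    for j in drift_idx:
        end = rng.uniform(*drift_amplitude)
        raw[:, j] = raw[:, j] * _drift_curve(u, end)
        drift_profile[feature_ids[j]] = {"end_multiplier": float(end), "shape": 1.0}

    # --- below-detection zeros ------------------------------------------
    # censoring at a global detection limit: the lowest zero_fraction of
    # all intensities fall below it and read out as 0
    if zero_fraction > 0:
        limit = np.quantile(raw, zero_fraction)
        raw[raw < limit] = 0.0

    matrix = FeatureMatrix(
        intensities=pd.DataFrame(raw, index=meta.index, columns=feature_ids),
        sample_meta=meta,
        ion_mode=ion_mode,
    )
    truth = PlantedTruth(
        differential_features={feature_ids[j]: float(lfc[j]) for j in diff_idx},
        associated_pairs=plants,
        drift_profile=drift_profile,
    )
    return matrix, truth


#: Reactome-style top-level / sub-pathway vocabulary for the fixture
PATHWAY_VOCABULARY: list[tuple[str, str]] = [
    ("Transport of small molecules", "SLC-mediated transmembrane transport"),
    ("Transport of small molecules", "ABC-family proteins mediated transport"),
    ("Signal transduction", "Signaling by GPCR"),
    ("Signal transduction", "Signaling by nuclear receptors"),
    ("Signal transduction", "Signaling by receptor tyrosine kinases"),
    ("Disease", "Disorders of transmembrane transporters"),
    ("Metabolism", "Metabolism of lipids"),
    ("Metabolism", "Metabolism of nucleotides"),
    ("Metabolism", "Metabolism of porphyrins"),
    ("Metabolism of proteins", "Translation"),
    ("Metabolism of proteins", "Peptide hormone metabolism"),
    ("Digestion and absorption", "Digestion"),
]

_SOURCES = ("KEGG", "Reactome", "WikiPathways")


def generate_pathway_fixture(
    metabolite_ids: Sequence[str],
    n_pathways: int = 20,
    size_range: tuple[int, int] = (5, 150),
    seed: int = 0,
    enriched_members: Sequence[str] = (),
    n_enriched: int = 0,
) -> PathwayFixture:
    """Sample annotation sets over a single metabolite id space.

    Sizes are uniform over ``size_range`` (clipped to the universe);
    members are drawn without replacement within a pathway and with
    replacement across pathways.  Labels cycle through a fixed
    Reactome-style top-level/sub-pathway vocabulary.  The first
    ``n_enriched`` pathways draw up to half their members from
    ``enriched_members`` (e.g. the planted differential set), giving
    the fixture known over-represented pathways.
    """
    lo, hi = size_range
    if lo < 1:
        raise ValueError("size_range lower bound must be >= 1")
    ids = list(metabolite_ids)
    if len(ids) < lo:
        raise ValueError("not enough metabolites to fill the requested sizes")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, min(hi, len(ids)) + 1))
        if i < n_enriched and len(enriched_members) >= 2:
            k = min(len(enriched_members), max(2, size // 2))
            core = rng.choice(sorted(enriched_members), size=k, replace=False).tolist()
            rest_pool = [m for m in ids if m not in set(core)]
            rest = rng.choice(rest_pool, size=size - k, replace=False).tolist()
            members = frozenset(core) | frozenset(rest)
        else:
            members = frozenset(rng.choice(ids, size=size, replace=False).tolist())
        top, sub = PATHWAY_VOCABULARY[i % len(PATHWAY_VOCABULARY)]
        source = _SOURCES[i % len(_SOURCES)]
        records.append(
            PathwayRecord(
                pathway_id=f"PW{i + 1:04d}",
                source=source,
                pathway_name=f"{sub} ({source} set {i + 1})",
                top_level=top,
                sub_pathway=sub,
                members=members,
            )
        )
    return PathwayFixture(records)
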