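"""Shared domain containers for the pharmacometabolomics pipeline.

The pipeline moves four kinds of objects between stages: per-subject
concentration-time profiles (into non-compartmental analysis), a
feature-intensity matrix with sample metadata (through preprocessing and
feature selection), association edges and their tripartite graph, and
pathway annotation sets.  Everything tabular is backed by pandas so the
on-disk CSV/TSV round trip is trivial.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectProfile",
    "PKModelParams",
    "ConcProfile",
    "FeatureMatrix",
    "AssociationPlant",
    "PlantedTruth",
    "PathwayRecord",
    "PathwayFixture",
    "DegenerateModelError",
]


class DegenerateModelError(ValueError):
    """Raised when ka == ke makes the one-compartment closed form singular."""


@dataclass
class SubjectProfile:
    """One study participant with demographics and clinical/laboratory values."""

    subject_id: str
    sex: str  # "F" or "M"
    age: float  # years
    bmi: float  # kg/m^2
    period: int  # crossover period label, 1 or 2
    characteristics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.bmi > 0:
            raise ValueError("bmi must be positive")
        if self.period not in (1, 2):
            raise ValueError("period must be 1 or 2")
        for name, value in self.characteristics.items():
            if not np.isfinite(value):
                raise ValueError(f"characteristic {name!r} is not finite")


@dataclass
class PKModelParams:
    """One-compartment oral-absorption model parameters.

    Defaults are calibrated so that the closed-form time of peak
    concentration is 7.50 h and the terminal half-life is 9.43 h
    (ln 2 / 9.43 = 0.0735 1/h), with a peak near 290 ng/mL for a
    100 mg (1e8 ng) dose and V/F = 2e5 mL.
    """

    dose: float = 1e8  # ng (100 mg)
    ka: float = 0.219  # 1/h absorption rate constant
    ke: float = 0.0735  # 1/h elimination rate constant
    v_over_f: float = 2e5  # mL apparent volume of distribution
    iiv_cv_ka: float = 0.30  # log-normal inter-individual CV on ka
    iiv_cv_ke: float = 0.25  # on ke
    iiv_cv_v: float = 0.25  # on V/F
    residual_cv: float = 0.0  # proportional assay noise CV

    def __post_init__(self) -> None:
        for name in ("dose", "ka", "ke", "v_over_f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.ka == self.ke:
            raise DegenerateModelError(
                "ka == ke: one-compartment closed form is singular; perturb one rate"
            )


@dataclass
class ConcProfile:
    """One subject's plasma concentration-time series (single oral dose)."""

    subject_id: str
    times: np.ndarray  # hours, strictly increasing, first = 0
    concentrations: np.ndarray  # ng/mL, nonnegative

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if self.times.size < 1 or self.times[0] != 0:
            raise ValueError("times must start at 0 (dosing time)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.concentrations[0] != 0:
            # expected 0 for a single oral dose; tolerate user data with
            # a baseline signal
            warnings.warn(
                f"{self.subject_id}: nonzero concentration at t=0 "
                "(expected 0 for a single oral dose)"
            )

    def __len__(self) -> int:
        return self.times.size


#: metadata columns required on every FeatureMatrix sample table
META_COLUMNS = ("subject_id", "phase", "injection_order")


@dataclass
class FeatureMatrix:
    """Samples x features intensity table with per-sample metadata.

    ``intensities`` is indexed by sample id; ``sample_meta`` shares that
    index and carries subject_id, phase ("pre" / "post" / "qc") and the
    (unique) injection order.  ``ion_mode`` labels the acquisition
    polarity of the whole matrix; modes are analyzed separately.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    ion_mode: str = "negative"
    is_scaled: bool = False  # log/Pareto-scaled matrices may go negative

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValueError("intensities and sample_meta must share the sample index")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError("ion_mode must be 'positive' or 'negative'")
        if not self.is_scaled and (np.asarray(self.intensities.values) < 0).any():
            raise ValueError("intensities must be nonnegative")
        order = self.sample_meta["injection_order"]
        if order.duplicated().any():
            raise ValueError("injection_order values must be unique")
        bio = self.sample_meta[self.sample_meta["phase"] != "qc"]
        counts = bio.groupby(["subject_id", "phase"]).size()
        if (counts != 1).any():
            raise ValueError("every non-QC subject must appear exactly once per phase")

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def is_qc(self) -> pd.Series:
        return self.sample_meta["phase"] == "qc"

    def qc_intensities(self) -> pd.DataFrame:
        return self.intensities.loc[self.is_qc]

    def biological_intensities(self) -> pd.DataFrame:
        return self.intensities.loc[~self.is_qc]

    def replace_intensities(
        self, values: pd.DataFrame, is_scaled: bool | None = None
    ) -> "FeatureMatrix":
        """Return a copy of this matrix with a new intensity table."""
        return FeatureMatrix(
            values,
            self.sample_meta.loc[values.index].copy(),
            self.ion_mode,
            self.is_scaled if is_scaled is None else is_scaled,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        return self.replace_intensities(self.intensities[list(feature_ids)].copy())

    def phase_abundance(self, phase: str) -> pd.DataFrame:
        """Subject-indexed abundance table for one biological phase."""
        if phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        mask = self.sample_meta["phase"] == phase
        out = self.intensities.loc[mask].copy()
        out.index = pd.Index(self.sample_meta.loc[mask, "subject_id"], name="subject_id")
        return out.sort_index()


@dataclass
class AssociationPlant:
    """One planted metabolite-target dependence of known strength."""

    feature_id: str
    target_name: str
    target_dcor: float  # requested distance correlation, in (0, 1]
    sign: int  # +1 or -1, direction of the Pearson coupling
    realized_dcor_pre: float = float("nan")
    realized_dcor_post: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 < self.target_dcor <= 1:
            raise ValueError("target_dcor must lie in (0, 1]")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generator for recovery checks."""

    differential_features: dict[str, float]  # feature id -> log-fold-change (ln scale)
    associated_pairs: list[AssociationPlant]
    drift_profile: dict[str, dict[str, float]]  # feature id -> drift parameters

    def to_json_dict(self) -> dict:
        return {
            "differential_features": self.differential_features,
            "associated_pairs": [dataclasses.asdict(p) for p in self.associated_pairs],
            "drift_profile": self.drift_profile,
        }


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    source: str  # KEGG / Reactome / WikiPathways
    pathway_name: str
    top_level: str
    sub_pathway: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("pathway members must be nonempty")


@dataclass
class PathwayFixture:
    """Bundled pathway annotation sets standing in for live database queries."""

    records: list[PathwayRecord]

    def __post_init__(self) -> None:
        keys = [(r.pathway_id, r.source) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("(pathway_id, source) pairs must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": [r.pathway_id for r in self.records],
                "source": [r.source for r in self.records],
                "pathway_name": [r.pathway_name for r in self.records],
                "top_level": [r.top_level for r in self.records],
                "sub_pathway": [r.sub_pathway for r in self.records],
                "members": [";".join(sorted(r.members)) for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayFixture":
        records = [
            PathwayRecord(
                pathway_id=row.pathway_id,
                source=row.source,
                pathway_name=row.pathway_name,
                top_level=row.top_level,
                sub_pathway=row.sub_pathway,
                members=frozenset(str(row.members).split(";")),
            )
            for row in frame.itertuples()
        ]
        return cls(records)
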