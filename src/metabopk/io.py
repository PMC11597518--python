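"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import ConcProfile, FeatureMatrix, PathwayFixture

__all__ = [
    "write_concentrations",
    "read_concentrations",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_characteristics",
    "read_characteristics",
    "write_pathway_fixture",
    "read_pathway_fixture",
    "write_truth",
]

_META_PREFIX = "meta_"


def write_concentrations(profiles: Sequence[ConcProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append({"subject_id": p.subject_id, "time_h": t, "conc_ng_ml": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_concentrations(path: str | Path) -> list[ConcProfile]:
    frame = pd.read_csv(path)
    profiles = []
    for sid, group in frame.groupby("subject_id", sort=True):
        group = group.sort_values("time_h")
        profiles.append(
            ConcProfile(
                subject_id=str(sid),
                times=group["time_h"].to_numpy(),
                concentrations=group["conc_ng_ml"].to_numpy(),
            )
        )
    return profiles


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """TSV with samples as rows; metadata columns are prefixed ``meta_``."""
    meta = matrix.sample_meta.add_prefix(_META_PREFIX)
    out = pd.concat([meta, matrix.intensities], axis=1)
    out.insert(0, f"{_META_PREFIX}ion_mode", matrix.ion_mode)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta_cols = [c for c in frame.columns if c.startswith(_META_PREFIX)]
    meta = frame[meta_cols].rename(columns=lambda c: c[len(_META_PREFIX):])
    ion_mode = str(meta.pop("ion_mode").iloc[0])
    meta["subject_id"] = meta["subject_id"].fillna("").astype(str)
    intensities = frame.drop(columns=meta_cols).astype(float)
    return FeatureMatrix(
        intensities=intensities,
        sample_meta=meta,
        ion_mode=ion_mode,
        is_scaled=bool((intensities.to_numpy() < 0).any()),
    )


def write_characteristics(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)


def read_characteristics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_pathway_fixture(fixture: PathwayFixture, path: str | Path) -> None:
    fixture.to_frame().to_csv(path, index=False)


def read_pathway_fixture(path: str | Path) -> PathwayFixture:
    return PathwayFixture.from_frame(pd.read_csv(path))


def write_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2))
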