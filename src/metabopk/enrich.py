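"""Metabolite-set over-representation and module integration.

Selected metabolites are tested against bundled pathway sets with the
one-sided hypergeometric (Fisher enrichment direction); the tested
family is the pathways whose background-intersected size falls within
the allowed range, and BH-FDR runs over exactly that family.  Retained
pathways (>= 2 hits, size within 5-150, q <= 0.05) are rolled up by a
top-level/sub-pathway hierarchy and joined to network modules: every
(parameter-or-characteristic, metabolite) pair that shares a Leiden
module and a retained association edge is reported with the retained
pathways containing that metabolite.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .datatypes import PathwayFixture
from .diffabund import adjust_bh
from .network import CommunityPartition

__all__ = [
    "FALLBACK_LABEL",
    "overrepresentation_test",
    "filter_pathways",
    "rollup_hierarchy",
    "integrate_modules_pathways",
]

FALLBACK_LABEL = "Individual evidence in the literature (N/A)"


def overrepresentation_test(
    selected_ids: set[str] | list[str],
    fixture: PathwayFixture,
    background_ids: set[str] | list[str],
    size_range: tuple[int, int] = (5, 150),
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per pathway.

    Pathway membership is intersected with the background before
    anything else; p = P(X >= k) for k hits out of n selected, K
    pathway members, N background metabolites.  Only pathways whose
    intersected size lies in ``size_range`` enter the BH family; the
    rest are excluded from the result entirely.
    """
    background = set(background_ids)
    if not background:
        raise ValueError("background is empty")
    selected = set(selected_ids)
    if not selected <= background:
        raise ValueError("selected ids must be a subset of the background")
    lo, hi = size_range
    rows = []
    for record in fixture.records:
        members = record.members & background
        size = len(members)
        if not lo <= size <= hi:
            continue
        hits = members & selected
        k, N, K, n = len(hits), len(background), size, len(selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway_id": record.pathway_id,
                "source": record.source,
                "pathway_name": record.pathway_name,
                "top_level": record.top_level,
                "sub_pathway": record.sub_pathway,
                "n_hits": k,
                "pathway_size": size,
                "background_size": N,
                "n_selected": n,
                "p_hyper": p,
                "hit_ids": ";".join(sorted(hits)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = adjust_bh(out["p_hyper"])
    else:
        out = pd.DataFrame(
            columns=[
                "pathway_id", "source", "pathway_name", "top_level", "sub_pathway",
                "n_hits", "pathway_size", "background_size", "n_selected",
                "p_hyper", "hit_ids", "q_bh",
            ]
        )
    return out


def filter_pathways(
    results: pd.DataFrame,
    min_hits: int = 2,
    size_range: tuple[int, int] = (5, 150),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Conjunction of the retention rules (order-independent).

    Retained iff n_hits >= ``min_hits``, pathway size within
    ``size_range``, and q <= ``alpha``.
    """
    lo, hi = size_range
    keep = (
        (results["n_hits"] >= min_hits)
        & (results["pathway_size"] >= lo)
        & (results["pathway_size"] <= hi)
        & (results["q_bh"] <= alpha)
    )
    return results[keep].reset_index(drop=True)


def rollup_hierarchy(retained: pd.DataFrame) -> pd.DataFrame:
    """Rank top-level pathway groups by distinct hit-metabolite count.

    Groups are ordered by decreasing number of distinct metabolites
    across their retained pathways, ties alphabetical; each row lists
    the group's sub-pathways.
    """
    if retained.empty:
        raise ValueError("no retained pathways to roll up")
    rows = []
    for top, group in retained.groupby("top_level"):
        members: set[str] = set()
        for hit_ids in group["hit_ids"]:
            if hit_ids:
                members |= set(hit_ids.split(";"))
        rows.append(
            {
                "top_level": top,
                "n_distinct_metabolites": len(members),
                "n_pathways": len(group),
                "sub_pathways": ";".join(sorted(group["sub_pathway"].unique())),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["n_distinct_metabolites", "top_level"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def _pathway_label(metabolite: str, retained: pd.DataFrame) -> str:
    labels = []
    for row in retained.itertuples():
        hits = set(row.hit_ids.split(";")) if row.hit_ids else set()
        if metabolite in hits:
            labels.append(f"{row.top_level} ({row.sub_pathway})")
    if not labels:
        return FALLBACK_LABEL
    return "/".join(sorted(set(labels)))


def integrate_modules_pathways(
    partition: CommunityPartition,
    edges: pd.DataFrame,
    retained: pd.DataFrame,
    phase: str | None = None,
) -> pd.DataFrame:
    """Join network modules to enriched pathways (integrated report).

    For every retained association edge whose metabolite and target
    share a Leiden module, emit one record naming the target, the
    metabolite, and each retained pathway containing the metabolite as
    "top_level (sub_pathway)" joined by "/"; metabolites absent from
    every retained pathway carry the literature fallback label.
    """
    rows = []
    kept = edges[edges["retained"]] if "retained" in edges.columns else edges
    for row in kept.itertuples():
        met, target = row.metabolite_id, row.target_name
        m_mod = partition.membership.get(met)
        t_mod = partition.membership.get(target)
        if m_mod is None or t_mod is None or m_mod != t_mod:
            continue
        rows.append(
            {
                "parameter_or_characteristic": target,
                "phase": phase if phase is not None else getattr(row, "phase", ""),
                "metabolite": met,
                "module": m_mod,
                "sign": row.sign,
                "top_level_pathways": _pathway_label(met, retained),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "parameter_or_characteristic", "phase", "metabolite",
            "module", "sign", "top_level_pathways",
        ],
    )
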