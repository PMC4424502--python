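"""End-to-end loop-motif discovery from matrices and interaction catalogs.

Chains the stages: per-time-point differential expression on both
platforms, entity classification, catalog restriction, fold-change profile
construction with least-squares imputation of the sparser platform, edge
correlation, loop enumeration/filtering, and network integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import (
    expression_processing as ep,
    interaction_catalog as ic,
    loop_inference as li,
    temporal_imputation as ti,
)
from .expression_processing import ExpressionMatrix
from .loop_inference import ClosedLoop

__all__ = ["TimepointResult", "fold_change_profiles", "analyze_timepoint"]


@dataclass
class TimepointResult:
    """Everything the pipeline derives for one reperfusion time point."""

    time_h: float
    de: pd.DataFrame               # classified DE table for this time point
    pairs: pd.DataFrame            # DE-restricted typed pairs
    candidates: list[ClosedLoop]   # enumerated loop candidates (scored)
    loops: list[ClosedLoop]        # loops with all three edges significant
    fraction_significant: float

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_loops(self) -> int:
        return len(self.loops)


def fold_change_profiles(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    entities,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Per-entity log2 fold-change (injured - sham) profiles on the union grid.

    The mRNA platform's missing time points are imputed by each entity's
    least-squares line; the result maps entity id -> value vector over the
    sorted union of both platforms' time points.
    """
    entities = set(entities)

    def measured(matrix: ExpressionMatrix) -> dict[str, list[tuple[float, float]]]:
        profs: dict[str, list[tuple[float, float]]] = {}
        for t in matrix.timepoints:
            de = ep.differential_expression(matrix, t, fc_threshold, alpha)
            for eid, lfc in zip(de["entity_id"], de["log2fc"]):
                if eid in entities:
                    profs.setdefault(eid, []).append((t, float(lfc)))
        return profs

    table = ti.build_matched_profiles(measured(mrna), measured(mirna))
    return ti.profiles_to_arrays(table)


def analyze_timepoint(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    catalogs,
    tf_ids,
    time_h: float,
    fc_threshold: float = 2.0,
    alpha_de: float = 0.05,
    alpha_edge: float = 0.05,
    combine: str = "or",
    positive_only: bool = False,
    n_perm: int = 1999,
    seed: int | None = None,
) -> TimepointResult:
    """Run the full discovery chain for one time point.

    ``catalogs`` is an iterable of pair DataFrames (or a dict of them) with
    columns ``source_id, target_id, provenance``; ``tf_ids`` the TF
    identifier list splitting the mRNA platform into TFs and plain mRNAs.
    """
    if isinstance(catalogs, dict):
        catalogs = list(catalogs.values())
    de_parts = [
        ep.differential_expression(mrna, time_h, fc_threshold, alpha_de),
        ep.differential_expression(mirna, time_h, fc_threshold, alpha_de)
        if time_h in mirna.timepoints
        else None,
    ]
    de = pd.concat([p for p in de_parts if p is not None], ignore_index=True)
    de = ep.classify_entities(de, tf_ids)

    pairs = ic.merge_pairs(*catalogs)
    restricted = ic.restrict_to_de(pairs, de, time_h)
    candidates = li.enumerate_candidate_loops(restricted)
    if candidates:
        members = sorted({e for c in candidates for e in c.key})
        profiles = fold_change_profiles(mrna, mirna, members, fc_threshold, alpha_de)
        candidates = li.score_loop_edges(
            candidates,
            profiles,
            time_h=time_h,
            alpha=alpha_edge,
            combine=combine,
            positive_only=positive_only,
            n_perm=n_perm,
            seed=seed,
        )
    loops, fraction = li.filter_significant_loops(candidates)
    return TimepointResult(
        time_h=time_h,
        de=de,
        pairs=restricted,
        candidates=candidates,
        loops=loops,
        fraction_significant=fraction,
    )
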