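"""Enumeration and filtering of miR-TF-gene closed loop-motifs.

A closed loop-motif is a tripartite pattern in which a miRNA targets a
transcription factor and both regulate a common gene: three nodes (miR, TF,
gene) joined by three edges (miR->TF, miR->gene, TF->gene).  Only this
topology is enumerated; a loop is retained when all three of its edges are
significantly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .edge_correlation import EdgeStats, score_edge
from .interaction_catalog import EDGE_MIR_GENE, EDGE_MIR_TF, EDGE_TF_GENE

__all__ = [
    "ClosedLoop",
    "enumerate_candidate_loops",
    "score_loop_edges",
    "filter_significant_loops",
    "loop_report",
    "loops_to_frame",
]


@dataclass(frozen=True)
class ClosedLoop:
    """One (miR, TF, gene) triple with its three scored edges."""

    mir: str
    tf: str
    gene: str
    time_h: float | None = None
    edge_mir_tf: EdgeStats | None = None
    edge_mir_gene: EdgeStats | None = None
    edge_tf_gene: EdgeStats | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mir, self.tf, self.gene)

    @property
    def edges(self) -> tuple[EdgeStats | None, ...]:
        return (self.edge_mir_tf, self.edge_mir_gene, self.edge_tf_gene)

    @property
    def significant(self) -> bool:
        return all(e is not None and e.significant for e in self.edges)


def enumerate_candidate_loops(pairs: pd.DataFrame) -> list[ClosedLoop]:
    """All (m, f, g) with miR->TF pair (m, f), miR->gene (m, g), TF->gene (f, g).

    Ordering is lexicographic by (mir, tf, gene) and deterministic.
    """
    if pairs.empty:
        return []
    by_class = {
        cls: set(zip(sub["source_id"], sub["target_id"]))
        for cls, sub in pairs.groupby("edge_class")
    }
    mir_tf = by_class.get(EDGE_MIR_TF, set())
    mir_gene = by_class.get(EDGE_MIR_GENE, set())
    tf_gene = by_class.get(EDGE_TF_GENE, set())
    if not (mir_tf and mir_gene and tf_gene):
        return []
    genes_of_mir: dict[str, set[str]] = {}
    for m, g in mir_gene:
        genes_of_mir.setdefault(m, set()).add(g)
    genes_of_tf: dict[str, set[str]] = {}
    for f, g in tf_gene:
        genes_of_tf.setdefault(f, set()).add(g)
    loops = []
    for m, f in mir_tf:
        shared = genes_of_mir.get(m, set()) & genes_of_tf.get(f, set())
        for g in shared:
            loops.append(ClosedLoop(mir=m, tf=f, gene=g))
    return sorted(loops, key=lambda l: l.key)


def score_loop_edges(
    candidates: list[ClosedLoop],
    profiles: dict,
    time_h: float | None = None,
    alpha: float = 0.05,
    combine: str = "or",
    positive_only: bool = False,
    n_perm: int = 1999,
    seed: int | None = None,
) -> list[ClosedLoop]:
    """Attach EdgeStats to every candidate, caching per distinct edge."""
    cache: dict[tuple[str, str, str], EdgeStats] = {}

    def scored(src: str, tgt: str, cls: str) -> EdgeStats:
        k = (src, tgt, cls)
        if k not in cache:
            cache[k] = score_edge(
                src, tgt, cls, profiles, alpha=alpha, combine=combine,
                positive_only=positive_only, n_perm=n_perm, seed=seed,
            )
        return cache[k]

    return [
        ClosedLoop(
            mir=c.mir, tf=c.tf, gene=c.gene, time_h=time_h,
            edge_mir_tf=scored(c.mir, c.tf, EDGE_MIR_TF),
            edge_mir_gene=scored(c.mir, c.gene, EDGE_MIR_GENE),
            edge_tf_gene=scored(c.tf, c.gene, EDGE_TF_GENE),
        )
        for c in candidates
    ]


def filter_significant_loops(candidates: list[ClosedLoop]) -> tuple[list[ClosedLoop], float]:
    """Keep loops whose three edges are all significant; return (kept, fraction kept)."""
    for c in candidates:
        for e, cls in zip(c.edges, (EDGE_MIR_TF, EDGE_MIR_GENE, EDGE_TF_GENE)):
            if e is None:
                raise ValueError(f"unscored {cls} edge on loop {c.key}")
    kept = [c for c in candidates if c.significant]
    fraction = len(kept) / len(candidates) if candidates else 0.0
    return kept, fraction


def loop_report(loops_by_timepoint: dict[float, list[ClosedLoop]]) -> pd.DataFrame:
    """Per-time-point counts of loops and distinct participating mRNAs, TFs, miRs."""
    rows = []
    for t in sorted(loops_by_timepoint):
        loops = loops_by_timepoint[t]
        rows.append(
            {
                "time_h": t,
                "loops": len(loops),
                "mRNA": len({l.gene for l in loops}),
                "TFs": len({l.tf for l in loops}),
                "miRs": len({l.mir for l in loops}),
            }
        )
    return pd.DataFrame(rows, columns=["time_h", "loops", "mRNA", "TFs", "miRs"])


def loops_to_frame(loops: list[ClosedLoop]) -> pd.DataFrame:
    """Flatten loops to a TSV-ready table, one row per loop."""
    rows = []
    for l in loops:
        row = {"mir": l.mir, "tf": l.tf, "gene": l.gene, "time_h": l.time_h,
               "significant": l.significant}
        for label, e in zip(("mir_tf", "mir_gene", "tf_gene"), l.edges):
            if e is not None:
                row[f"r_{label}"] = e.r
                row[f"p_pearson_{label}"] = e.p_pearson
                row[f"dcor_{label}"] = e.dcor
                row[f"p_dcor_{label}"] = e.p_dcor
        rows.append(row)
    return pd.DataFrame(rows)
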