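"""Homology-filter cascade: sequential elimination against a reference panel.

A gene is eliminated at the first database stage where it has at least one
significant hit (E-value <= cutoff, inclusive); survivors of every stage
are the orphan genes (OGs), everything else non-orphan genes (NOGs).
Because elimination is "hit anywhere", the final OG set is invariant under
permutation of the panel order; only the stage-eliminated labels change.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import HomologyHit, SearchParams, search
from .seq_io import GeneModel, ReferenceDB

__all__ = ["CascadeResult", "CascadeSummary", "run_cascade", "orphan_content"]


@dataclass
class CascadeResult:
    """Per-gene audit trail of the cascade."""

    gene_id: str
    stage_eliminated: str | None    # database name, or None for orphans
    best_hit: HomologyHit | None

    @property
    def is_orphan(self) -> bool:
        return self.stage_eliminated is None


@dataclass
class CascadeSummary:
    results: list[CascadeResult]
    stage_names: list[str]
    survivors_per_stage: list[int]  # after each stage, non-increasing

    @property
    def orphan_ids(self) -> list[str]:
        return [r.gene_id for r in self.results if r.is_orphan]


def run_cascade(proteome: list[GeneModel] | list[tuple[str, str]],
                panel: list[ReferenceDB],
                evalue_cutoff: float = 1e-5,
                params: SearchParams | None = None) -> CascadeSummary:
    """Run the sequential homology filter over an ordered database panel.

    ``proteome`` may be GeneModels or plain (id, protein) pairs. Panel
    databases are visited in ``stage_rank`` order; only survivors of a
    stage are queried at the next one. Self-hits (subject ID equal to the
    query gene ID) never eliminate a gene: the reference panel represents
    *other* species and databases, and a query's own record slipping into
    one must not disqualify it.
    """
    if not panel:
        raise ValueError("cascade undefined for an empty panel")
    ranks = [db.stage_rank for db in panel]
    if len(set(ranks)) != len(ranks):
        raise ValueError("panel stage_ranks must be strictly ordered (unique)")
    panel = sorted(panel, key=lambda db: db.stage_rank)

    queries: list[tuple[str, str]] = []
    for entry in proteome:
        if isinstance(entry, GeneModel):
            queries.append((entry.gene_id, entry.protein_seq.rstrip("*")))
        else:
            gid, seq = entry
            queries.append((gid, seq.rstrip("*")))
    for gid, seq in queries:
        if not seq:
            raise ValueError(f"{gid}: empty protein sequence")

    params = params or SearchParams(mode="protein", evalue_cutoff=evalue_cutoff)
    params.evalue_cutoff = evalue_cutoff

    results: dict[str, CascadeResult] = {}
    survivors = queries
    survivors_per_stage: list[int] = []
    for db in panel:
        next_survivors = []
        for gid, seq in survivors:
            hits = [h for h in search(gid, seq, db, params) if h.subject_id != gid]
            if hits:
                results[gid] = CascadeResult(gid, db.name, hits[0])
            else:
                next_survivors.append((gid, seq))
        survivors = next_survivors
        survivors_per_stage.append(len(survivors))
    for gid, _seq in survivors:
        results[gid] = CascadeResult(gid, None, None)
    ordered = [results[gid] for gid, _ in queries]
    return CascadeSummary(results=ordered,
                          stage_names=[db.name for db in panel],
                          survivors_per_stage=survivors_per_stage)


def orphan_content(summary: CascadeSummary) -> tuple[int, int, float]:
    """(orphan count, proteome size, orphan percentage of the proteome)."""
    if not summary.results:
        raise ValueError("empty cascade result")
    n_og = sum(r.is_orphan for r in summary.results)
    n = len(summary.results)
    return n_og, n, 100.0 * n_og / n
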