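"""Origin-mechanism classification for orphan genes.

Each orphan gene (OG) is assigned exactly one of five mechanisms, tested in
a fixed precedence order: gene duplication (with one of five modes), gene
overlap with another species' CDS, transposable-element (TE) exaptation,
de novo origin from non-coding sequence, or unclassified. Duplications are
dated through Nei-Gojobori synonymous distance (Ks) and a molecular clock
T = Ks / (2 mu) with the universal plant rate mu = 6.5e-9 substitutions
per site per year.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .homology import SearchParams, coverage_of, search, translate_frame
from .seq_io import GeneModel, GenomePackage, ReferenceDB

__all__ = [
    "OriginCall",
    "CollinearBlock",
    "OriginContext",
    "paralog_pairs",
    "collinear_blocks",
    "classify_duplication",
    "nei_gojobori_ks",
    "date_duplication",
    "overlap_origin",
    "te_origin",
    "de_novo_origin",
    "classify_origins",
    "ancestral_locus_set",
]

MU_DEFAULT = 6.5e-9   # substitutions / synonymous site / year

_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class OriginCall:
    gene_id: str
    mechanism: str                  # duplication | overlap | te | de_novo | unclassified
    dup_mode: str | None = None     # tandem | proximal | dispersed | wgd | transposed
    partner_id: str | None = None
    ks: float | None = None
    ka: float | None = None
    age_mya: float | None = None
    evidence: dict = field(default_factory=dict)


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]  # ordered (gene_a, gene_b) pairs
    orientation: int                # +1 parallel, -1 inverted

    @property
    def size(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ks / Ka
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous / nonsynonymous site counts of one codon.

    A change creating a stop codon counts as nonsynonymous (standard NG86
    convention)."""
    aa = _CODON_TABLE.get(codon)
    if aa is None:
        raise ValueError(f"cannot count sites of codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        s = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _CODON_TABLE[alt] == aa:
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous differences between two codons.

    Averages with equal weight over all minimal mutation pathways that do
    not pass through a stop codon; if every pathway is blocked, all
    pathways are used (degenerate fallback)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            pathways.append((sd, nd))
    if not pathways:
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                same = (_CODON_TABLE.get(cur) == _CODON_TABLE.get(nxt)
                        and cur not in _STOPS and nxt not in _STOPS)
                if same:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            pathways.append((sd, nd))
    sd = float(np.mean([p[0] for p in pathways]))
    nd = float(np.mean([p[1] for p in pathways]))
    return sd, nd


_PROT_ALIGNER = PairwiseAligner()
_PROT_ALIGNER.mode = "global"
_PROT_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_PROT_ALIGNER.open_gap_score = -12
_PROT_ALIGNER.extend_gap_score = -1


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon-level alignment from a global protein alignment, back-threaded.

    Gap columns are dropped pairwise; codons containing ambiguity codes or
    stops are skipped."""
    pa, pb = _cds_to_protein(cds_a), _cds_to_protein(cds_b)
    aln = _PROT_ALIGNER.align(pa, pb)[0]
    sa, sb = str(aln[0]), str(aln[1])
    pairs = []
    ia = ib = 0
    for x, y in zip(sa, sb):
        if x != "-" and y != "-":
            ca = cds_a[3 * ia:3 * ia + 3].upper()
            cb = cds_b[3 * ib:3 * ib + 3].upper()
            if (len(ca) == 3 and len(cb) == 3
                    and set(ca) <= set(_BASES) and set(cb) <= set(_BASES)
                    and ca not in _STOPS and cb not in _STOPS):
                pairs.append((ca, cb))
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return pairs


def _cds_to_protein(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3].upper()
        if codon in _STOPS:
            break
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def nei_gojobori_ks(cds_a: str, cds_b: str, aligned: bool = False):
    """Nei-Gojobori (pathway-averaged, Jukes-Cantor corrected) Ks and Ka.

    Returns a dict with keys ks, ka, ps, pn, S, N; ks/ka are None when the
    proportion of differences saturates the Jukes-Cantor correction
    (p >= 3/4) or when the corresponding site count is zero.

    When ``aligned`` is false the CDSs are codon-aligned through a global
    protein alignment first.
    """
    if aligned:
        if len(cds_a) != len(cds_b) or len(cds_a) % 3:
            raise ValueError("aligned CDSs must have equal, codon-multiple length")
        pairs = []
        for i in range(0, len(cds_a), 3):
            ca, cb = cds_a[i:i + 3].upper(), cds_b[i:i + 3].upper()
            if (set(ca) <= set(_BASES) and set(cb) <= set(_BASES)
                    and ca not in _STOPS and cb not in _STOPS):
                pairs.append((ca, cb))
    else:
        pairs = codon_align(cds_a, cds_b)
    if not pairs:
        raise ValueError("no alignable codons")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    return {"ks": ks, "ka": ka, "ps": ps, "pn": pn, "S": S, "N": N,
            "Sd": Sd, "Nd": Nd, "codons": len(pairs)}


def _jukes_cantor(p: float | None) -> float | None:
    if p is None or p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def date_duplication(ks: float, mu: float = MU_DEFAULT) -> float:
    """Molecular-clock age in MYA: T = Ks / (2 mu), years scaled by 1e6."""
    if ks is None or ks < 0:
        raise ValueError("ks must be a defined non-negative value")
    return ks / (2.0 * mu) / 1e6


# ---------------------------------------------------------------------------
# Duplication-mode machinery
# ---------------------------------------------------------------------------

def paralog_pairs(proteome: list[tuple[str, str]],
                  evalue: float = 1e-8) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Within-genome reciprocal paralog pairs at E <= ``evalue``.

    Returns (pairs, best_partner) where pairs are unordered (a < b) tuples
    with reciprocal significant hits, self-pairs excluded, and
    best_partner maps each gene to its highest-bit-score partner.
    """
    if len(proteome) < 2:
        return [], {}
    db = ReferenceDB(name="self", kind="protein", records=list(proteome))
    params = SearchParams(mode="protein", evalue_cutoff=evalue)
    hits_by_pair: dict[tuple[str, str], float] = {}
    directed: set[tuple[str, str]] = set()
    for gid, seq in proteome:
        if not seq:
            continue
        for h in search(gid, seq, db, params):
            if h.subject_id == gid:
                continue
            directed.add((gid, h.subject_id))
            key = tuple(sorted((gid, h.subject_id)))
            prev = hits_by_pair.get(key, -math.inf)
            hits_by_pair[key] = max(prev, h.bit_score)
    pairs = [key for key in sorted(hits_by_pair)
             if (key[0], key[1]) in directed and (key[1], key[0]) in directed]
    best: dict[str, str] = {}
    best_score: dict[str, float] = {}
    for a, b in pairs:
        s = hits_by_pair[(a, b)]
        for g, p in ((a, b), (b, a)):
            if s > best_score.get(g, -math.inf):
                best_score[g] = s
                best[g] = p
    return pairs, best


def gene_ranks(genes: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene_id -> (chromosome, rank) with rank the start-order index."""
    ranks: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, glist in by_chrom.items():
        for i, g in enumerate(sorted(glist, key=lambda x: x.start)):
            ranks[g.gene_id] = (chrom, i)
    return ranks


def collinear_blocks(anchor_pairs: list[tuple[str, str]],
                     ranks: dict[str, tuple[str, int]],
                     ranks_b: dict[str, tuple[str, int]] | None = None,
                     min_anchors: int = 5,
                     max_gap: int = 25) -> list[CollinearBlock]:
    """Chain anchor pairs into collinear blocks by rank-gap-bounded DP.

    Anchors are (gene_a, gene_b) pairs; ``ranks`` gives (chromosome, rank)
    for the first member and ``ranks_b`` (defaults to ``ranks``) for the
    second. Within one chromosome pair, a chain must be strictly increasing
    in rank on the first axis and strictly monotone (either direction) on
    the second, with rank gaps <= ``max_gap`` on both axes. Maximal chains
    are extracted greedily by size; chains shorter than ``min_anchors`` are
    discarded.
    """
    symmetric = ranks_b is None
    if ranks_b is None:
        ranks_b = ranks
    grouped: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in anchor_pairs:
        if a not in ranks or b not in ranks_b:
            continue
        ca, ra = ranks[a]
        cb, rb = ranks_b[b]
        if symmetric and (cb, rb) < (ca, ra):
            # canonical orientation so symmetric pairs group consistently
            (ca, ra, a), (cb, rb, b) = (cb, rb, b), (ca, ra, a)
        grouped.setdefault((ca, cb), []).append((ra, rb, a, b))
    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(grouped.items()):
        remaining = sorted(set(anchors))
        while True:
            chain, orient = _best_chain(remaining, max_gap)
            if len(chain) < min_anchors:
                break
            blocks.append(CollinearBlock(
                chrom_a=ca, chrom_b=cb,
                anchors=[(a, b) for _ra, _rb, a, b in chain],
                orientation=orient))
            used = set(chain)
            remaining = [x for x in remaining if x not in used]
    blocks.sort(key=lambda bl: -bl.size)
    return blocks


def _best_chain(anchors, max_gap):
    """Largest gap-bounded monotone chain (O(n^2) DP), trying both
    orientations of the second axis."""
    best_chain: list = []
    best_orient = 1
    for orient in (1, -1):
        pts = sorted((ra, orient * rb, a, b) for ra, rb, a, b in anchors)
        n = len(pts)
        score = [1] * n
        prev = [-1] * n
        for j in range(n):
            for i in range(j):
                if (pts[i][0] < pts[j][0] and pts[i][1] < pts[j][1]
                        and pts[j][0] - pts[i][0] <= max_gap
                        and pts[j][1] - pts[i][1] <= max_gap
                        and score[i] + 1 > score[j]):
                    score[j] = score[i] + 1
                    prev[j] = i
        if n:
            jbest = max(range(n), key=lambda j: (score[j], -pts[j][0]))
            chain = []
            j = jbest
            while j != -1:
                ra, rb, a, b = pts[j]
                chain.append((ra, orient * rb, a, b))
                j = prev[j]
            chain.reverse()
            if len(chain) > len(best_chain):
                best_chain = chain
                best_orient = orient
    return best_chain, best_orient


def classify_duplication(pair: tuple[str, str],
                         ranks: dict[str, tuple[str, int]],
                         blocks: list[CollinearBlock],
                         proximal_window: int = 10,
                         ancestral_loci: set[str] | None = None) -> str:
    """Assign one of the five duplication modes to a paralog pair.

    Precedence: WGD (both genes anchors of one collinear block) > tandem
    (same chromosome, adjacent gene ranks) > proximal (rank distance
    2..``proximal_window``) > transposed (exactly one gene at an ancestral
    locus; evaluated only when ``ancestral_loci`` from an outgroup is
    supplied) > dispersed.
    """
    a, b = pair
    if a not in ranks or b not in ranks:
        raise KeyError(f"pair {pair}: gene on unannotated chromosome")
    for bl in blocks:
        anchor_set = {frozenset(p) for p in bl.anchors}
        if frozenset(pair) in anchor_set:
            return "wgd"
    ca, ra = ranks[a]
    cb, rb = ranks[b]
    if ca == cb:
        d = abs(ra - rb)
        if d == 1:
            return "tandem"
        if 2 <= d <= proximal_window:
            return "proximal"
    if ancestral_loci is not None:
        in_a, in_b = a in ancestral_loci, b in ancestral_loci
        if in_a != in_b:
            return "transposed"
    return "dispersed"


def ancestral_locus_set(package: GenomePackage, outgroup: GenomePackage,
                        evalue: float = 1e-8, min_anchors: int = 5,
                        max_gap: int = 25) -> set[str]:
    """Genes of ``package`` with a collinear match in an outgroup genome.

    Cross-species anchors are best reciprocal protein hits; anchors are
    chained with the same collinearity model used within the genome. A gene
    appearing as an anchor of a cross-species block sits at its ancestral
    locus.
    """
    out_db = ReferenceDB(name=f"outgroup:{outgroup.species_id}", kind="protein",
                         records=outgroup.proteome())
    params = SearchParams(mode="protein", evalue_cutoff=evalue)
    anchors: list[tuple[str, str]] = []
    for gid, seq in package.proteome():
        if not seq:
            continue
        hits = search(gid, seq, out_db, params)
        if hits:
            anchors.append((gid, hits[0].subject_id))
    blocks = collinear_blocks(anchors, gene_ranks(package.genes),
                              ranks_b=gene_ranks(outgroup.genes),
                              min_anchors=min_anchors, max_gap=max_gap)
    return {a for bl in blocks for a, _b in bl.anchors}


# ---------------------------------------------------------------------------
# Non-duplication origin rules
# ---------------------------------------------------------------------------

def overlap_origin(og: GeneModel, other_cds: ReferenceDB,
                   evalue: float = 1e-5, min_coverage: float = 0.5):
    """Gene-overlap rule: other-species CDS hits covering >= half the OG CDS.

    Coverage is the span union of all significant nucleotide hits over the
    OG CDS length."""
    params = SearchParams(mode="nucleotide", evalue_cutoff=evalue)
    hits = search(og.gene_id, og.cds_seq, other_cds, params)
    if not hits:
        return False, {"coverage": 0.0, "n_hits": 0}
    cov = coverage_of(hits, len(og.cds_seq))
    return cov >= min_coverage, {"coverage": cov, "n_hits": len(hits),
                                 "best_evalue": hits[0].evalue}


def te_origin(og_cds: str, te_library: ReferenceDB | list[tuple[str, str]] | None,
              evalue: float = 1e-5):
    """TE-exaptation rule: any significant nucleotide hit to the TE library."""
    if te_library is None:
        return False, {"n_hits": 0}
    if not isinstance(te_library, ReferenceDB):
        if not te_library:
            return False, {"n_hits": 0}
        te_library = ReferenceDB(name="te", kind="nucleotide",
                                 records=list(te_library))
    params = SearchParams(mode="nucleotide", evalue_cutoff=evalue)
    hits = search("og", og_cds, te_library, params)
    if not hits:
        return False, {"n_hits": 0}
    return True, {"n_hits": len(hits), "best_evalue": hits[0].evalue,
                  "te_id": hits[0].subject_id}


def de_novo_origin(og: GeneModel, other_genomes: list[ReferenceDB],
                   evalue: float = 1e-6, min_identity: float = 60.0,
                   min_coverage: float = 0.8, orf_fraction: float = 0.5):
    """De novo rule: an alignable but non-coding orthologous region.

    True iff some other genome has a translated (protein-vs-six-frame) hit
    with identity >= 60 %, query coverage >= 80 % and E <= 1e-6, whose
    hit-frame open reading frame terminates prematurely below half the OG
    protein length.
    """
    protein = og.protein_seq.rstrip("*")
    if not protein:
        return False, {}
    params = SearchParams(mode="translated", evalue_cutoff=evalue)
    for db in other_genomes:
        hits = search(og.gene_id, protein, db, params)
        for h in hits:
            if h.percent_identity < min_identity:
                continue
            if h.query_coverage(len(protein)) < min_coverage:
                continue
            orf_len = _orf_length_from_hit(h, db)
            if orf_len < orf_fraction * len(protein):
                return True, {"genome": db.name, "subject": h.subject_id,
                              "identity": h.percent_identity,
                              "coverage": h.query_coverage(len(protein)),
                              "evalue": h.evalue, "orf_aa": orf_len}
    return False, {}


def _orf_length_from_hit(hit, db: ReferenceDB) -> int:
    """Residues from the hit's frame-start until the first stop codon."""
    seq = dict(db.records)[hit.subject_id]
    if hit.frame < 0:
        from .seq_io import reverse_complement
        seq = reverse_complement(seq)
    aa = translate_frame(seq, abs(hit.frame) - 1)
    start = (hit.subject_aa_span[0] - 1) if hit.subject_aa_span else 0
    stop = aa.find("*", start)
    end = stop if stop != -1 else len(aa)
    return end - start


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class OriginContext:
    """Everything the origin classifiers need beyond the focal package."""

    other_cds: ReferenceDB | None = None          # other-species CDS (nucleotide)
    te_library: ReferenceDB | None = None
    other_genomes: list[ReferenceDB] = field(default_factory=list)  # nucleotide
    outgroup: GenomePackage | None = None
    paralog_evalue: float = 1e-8
    overlap_evalue: float = 1e-5
    te_evalue: float = 1e-5
    de_novo_evalue: float = 1e-6
    proximal_window: int = 10
    min_anchors: int = 5
    max_gap: int = 25
    mu: float = MU_DEFAULT


def classify_origins(og_ids: list[str], package: GenomePackage,
                     context: OriginContext) -> tuple[list[OriginCall], dict[str, int]]:
    """Assign one origin mechanism to every OG, in precedence order.

    Precedence duplication > overlap > te > de_novo > unclassified follows
    the order in which the mechanisms are tested; each OG receives exactly
    one mechanism. Returns the calls plus a mechanism/mode count table.
    """
    proteome = package.proteome()
    pairs, best_partner = paralog_pairs(proteome, evalue=context.paralog_evalue)
    ranks = gene_ranks(package.genes)
    blocks = collinear_blocks(pairs, ranks, min_anchors=context.min_anchors,
                              max_gap=context.max_gap)
    ancestral = None
    if context.outgroup is not None:
        ancestral = ancestral_locus_set(package, context.outgroup,
                                        evalue=context.paralog_evalue,
                                        min_anchors=context.min_anchors,
                                        max_gap=context.max_gap)
    calls: list[OriginCall] = []
    for gid in og_ids:
        gene = package.gene(gid)
        partner = best_partner.get(gid)
        if partner is not None:
            mode = classify_duplication((gid, partner), ranks, blocks,
                                        proximal_window=context.proximal_window,
                                        ancestral_loci=ancestral)
            ng = None
            try:
                ng = nei_gojobori_ks(gene.cds_seq, package.gene(partner).cds_seq)
            except ValueError:
                pass
            ks = ng["ks"] if ng else None
            calls.append(OriginCall(
                gene_id=gid, mechanism="duplication", dup_mode=mode,
                partner_id=partner, ks=ks, ka=ng["ka"] if ng else None,
                age_mya=date_duplication(ks, context.mu) if ks is not None else None,
                evidence={"saturated": bool(ng and ng["ks"] is None)}))
            continue
        if context.other_cds is not None:
            ok, ev = overlap_origin(gene, context.other_cds,
                                    evalue=context.overlap_evalue)
            if ok:
                calls.append(OriginCall(gene_id=gid, mechanism="overlap", evidence=ev))
                continue
        if context.te_library is not None:
            ok, ev = te_origin(gene.cds_seq, context.te_library,
                               evalue=context.te_evalue)
            if ok:
                calls.append(OriginCall(gene_id=gid, mechanism="te", evidence=ev))
                continue
        if context.other_genomes:
            ok, ev = de_novo_origin(gene, context.other_genomes,
                                    evalue=context.de_novo_evalue)
            if ok:
                calls.append(OriginCall(gene_id=gid, mechanism="de_novo", evidence=ev))
                continue
        calls.append(OriginCall(gene_id=gid, mechanism="unclassified"))

    counts: dict[str, int] = {}
    for c in calls:
        key = f"duplication:{c.dup_mode}" if c.mechanism == "duplication" else c.mechanism
        counts[key] = counts.get(key, 0) + 1
    return calls, counts
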