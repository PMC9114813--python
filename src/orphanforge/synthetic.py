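"""Synthetic genome packages, reference panels and count matrices with
planted ground truth.

Every downstream stage of the pipeline is testable offline against these
generators: the cascade against planted no-homolog orphans, the duplication
classifier against planted pairs of each mode, the TE / overlap / de novo
rules against constructed cases, and the expression stack against
negative-binomial counts with planted tissue-specific and differentially
expressed genes. The same seed always yields byte-identical output.

Design notes
------------
* Intergenic background is i.i.d. uniform nucleotides; compositional
  realism is out of scope.
* Duplicate pairs are created by mutating a parent CDS at synonymous sites
  only, to a target Ks under the Jukes-Cantor mapping; Ka stays ~0, which
  is all the dating pipeline needs.
* TE-derived genes embed >= 60 % of their CDS in a TE-library record, so
  the TE rule is decidable by construction; de novo cases exist in partner
  genomes as high-identity regions with an in-frame premature stop.
* Orphan genes are random-codon sequences excluded from every reference
  database; each non-orphan carries a homolog (~80 % identity) at exactly
  one planted panel stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .origins import OriginContext, _codon_sites
from .seq_io import GeneModel, GenomePackage, ReferenceDB, reverse_complement, translate

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_package",
    "simulate_reference_panel",
    "simulate_origin_context",
    "simulate_study",
    "simulate_counts",
    "simulate_de_counts",
    "simulate_trends",
    "simulate_module_blocks",
]

_BASES = "ACGT"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]
from Bio.Data.CodonTable import standard_dna_table as _TBL
_AA_OF = {c: _TBL.forward_table[c] for c in _SENSE_CODONS}
_CODONS_OF_AA: dict[str, list[str]] = {}
for _c, _a in _AA_OF.items():
    _CODONS_OF_AA.setdefault(_a, []).append(_c)


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome package.

    Counts are *pairs* for ``duplication_plan`` (both members of a planted
    pair are orphans) and genes otherwise. Defaults give 1,000 genes with
    50 planted orphans: 30 duplication (3 pairs of each of the five modes),
    5 TE-derived, 5 overlap, 5 de novo and 5 unclassifiable.
    """

    seed: int = 0
    n_genes: int = 1000
    n_chromosomes: int = 4
    duplication_plan: dict[str, int] = field(default_factory=lambda: {
        "tandem": 3, "proximal": 3, "dispersed": 3, "wgd": 3, "transposed": 3})
    te_gene_count: int = 5
    overlap_gene_count: int = 5
    denovo_gene_count: int = 5
    plain_orphan_count: int = 5
    homolog_identity: float = 0.80       # protein identity of panel homologs
    pair_identity: float = 1.0           # protein identity within duplicate pairs
    ks_range: tuple[float, float] = (0.10, 0.50)
    stage_probs: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)
    stage_names: tuple[str, ...] = ("cucurbit_proteomes", "plant_proteomes",
                                    "plant_puts", "uniprot_nr")
    decoys_per_db: int = 40
    orphan_codons: tuple[int, int] = (45, 100)
    nog_codons: tuple[int, int] = (150, 450)
    pair_codons: tuple[int, int] = (150, 250)
    wgd_run_length: int = 6              # anchor pairs per planted block
    event_spacing: tuple[int, int] = (30, 40)   # plain genes between events
    outgroup_divergence: float = 0.07    # nt mutation rate for outgroup copies

    def validate(self) -> None:
        n_special = (self.orphan_count
                     + 2 * (self.wgd_run_length - 1) * self.duplication_plan.get("wgd", 0))
        if n_special > self.n_genes:
            raise ValueError("special genes exceed n_genes; infeasible placement")
        if not math.isclose(sum(self.stage_probs), 1.0, abs_tol=1e-9):
            raise ValueError("stage_probs must sum to 1")
        if len(self.stage_probs) != len(self.stage_names):
            raise ValueError("one stage probability per stage name")

    @property
    def orphan_count(self) -> int:
        return (2 * sum(self.duplication_plan.values())
                + self.te_gene_count + self.overlap_gene_count
                + self.denovo_gene_count + self.plain_orphan_count)


@dataclass
class _GeneSpec:
    gene_id: str
    category: str               # nog | anchor | tandem | proximal | ... | plain_orphan
    cds: str
    is_orphan: bool
    origin_mode: str | None = None
    partner: str | None = None
    planted_ks: float | None = None
    stage: str | None = None    # panel stage for non-orphans
    in_outgroup: bool = False


@dataclass
class SimResult:
    package: GenomePackage
    truth: pd.DataFrame
    panel: list[ReferenceDB]
    context: OriginContext
    outgroup: GenomePackage | None


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=max(1, n_codons - 2))
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + "TAA"


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _mutate_protein(rng: np.random.Generator, protein: str, identity: float) -> str:
    """Substitute residues uniformly to reach the target identity."""
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    out = list(protein)
    n_mut = int(round((1.0 - identity) * len(protein)))
    for i in rng.choice(len(protein), size=min(n_mut, len(protein)), replace=False):
        choices = [a for a in aas if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _mutate_nt(rng: np.random.Generator, cds: str, rate: float,
               keep_frame_open: bool = True) -> str:
    """Random nucleotide substitutions; optionally refuse in-frame stops."""
    out = list(cds)
    n_mut = int(round(rate * len(cds)))
    positions = rng.choice(len(cds), size=min(n_mut, len(cds)), replace=False)
    for i in positions:
        alts = [b for b in _BASES if b != out[i]]
        b = alts[rng.integers(3)]
        old = out[i]
        out[i] = b
        if keep_frame_open:
            cstart = (i // 3) * 3
            codon = "".join(out[cstart:cstart + 3])
            if len(codon) == 3 and codon in _STOPS:
                out[i] = old
    return "".join(out)


def _synonymous_sites(cds: str) -> float:
    s = 0.0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3]
        if codon in _STOPS or codon not in _AA_OF:
            continue
        s += _codon_sites(codon)[0]
    return s


def _mutate_to_ks(rng: np.random.Generator, cds: str, target_ks: float) -> str:
    """Apply synonymous substitutions hitting the Jukes-Cantor-mapped
    proportion p = 3/4 (1 - exp(-4 Ks / 3)) of synonymous sites."""
    s_sites = _synonymous_sites(cds)
    p = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    n_target = int(round(p * s_sites))
    out = list(cds)
    codon_idx = list(range(len(cds) // 3))
    rng.shuffle(codon_idx)
    done = 0
    for ci in codon_idx:
        if done >= n_target:
            break
        codon = "".join(out[3 * ci:3 * ci + 3])
        if codon in _STOPS or codon not in _AA_OF:
            continue
        aa = _AA_OF[codon]
        # single-nt synonymous neighbours
        options = []
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt not in _STOPS and _AA_OF.get(alt) == aa:
                    options.append((pos, b))
        if not options:
            continue
        pos, b = options[rng.integers(len(options))]
        out[3 * ci + pos] = b
        done += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# package simulation
# ---------------------------------------------------------------------------

def simulate_package(config: SimConfig) -> tuple[GenomePackage, pd.DataFrame]:
    """Simulate one genome package and its per-gene truth table.

    Genes are laid out chromosome by chromosome with random intergenic
    spacers; planted structures respect their defining geometry (tandem
    pairs adjacent in gene-rank order, proximal pairs 2..10 ranks apart,
    WGD pairs inside collinear anchor runs, transposed/dispersed pairs on
    different chromosomes) and events on the same chromosome are separated
    by enough plain genes that no spurious collinearity can arise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs, te_library, chrom_lists = _plan_genes(config, rng)
    package = _emit_genome(config, rng, specs, te_library, chrom_lists)
    truth = pd.DataFrame([{
        "gene_id": s.gene_id, "category": s.category, "is_orphan": s.is_orphan,
        "origin_mode": s.origin_mode, "partner": s.partner,
        "planted_ks": s.planted_ks, "stage": s.stage,
    } for s in specs]).set_index("gene_id", drop=False)
    return package, truth


def _plan_genes(config: SimConfig, rng: np.random.Generator):
    specs: dict[str, _GeneSpec] = {}
    chrom_lists: list[list[str]] = [[] for _ in range(config.n_chromosomes)]
    te_library: list[tuple[str, str]] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"g{counter[0]:05d}"

    def make_plain_nog() -> _GeneSpec:
        n = int(rng.integers(*config.nog_codons))
        s = _GeneSpec(new_id(), "nog", _random_cds(rng, n), False, in_outgroup=True)
        specs[s.gene_id] = s
        return s

    n_special = config.orphan_count + (
        2 * (config.wgd_run_length - 1) * config.duplication_plan.get("wgd", 0))
    n_plain = config.n_genes - n_special
    plain_pool = [make_plain_nog() for _ in range(n_plain)]
    pool_iter = iter(plain_pool)

    def spacer(chrom: int) -> None:
        k = int(rng.integers(*config.event_spacing))
        for _ in range(k):
            s = next(pool_iter, None)
            if s is None:
                return
            chrom_lists[chrom].append(s.gene_id)

    chrom_cycle = [0]

    def next_chrom() -> int:
        c = chrom_cycle[0] % config.n_chromosomes
        chrom_cycle[0] += 1
        return c

    def orphan_cds(codon_range=None) -> str:
        lo, hi = codon_range or config.orphan_codons
        return _random_cds(rng, int(rng.integers(lo, hi)))

    def plant_pair(mode: str) -> None:
        n = int(rng.integers(*config.pair_codons))
        ks = float(rng.uniform(*config.ks_range))
        parent = _random_cds(rng, n)
        child = _mutate_to_ks(rng, parent, ks)
        a = _GeneSpec(new_id(), mode, parent, True,
                      origin_mode=f"duplication:{mode}", planted_ks=ks)
        b = _GeneSpec(new_id(), mode, child, True,
                      origin_mode=f"duplication:{mode}", planted_ks=ks)
        a.partner, b.partner = b.gene_id, a.gene_id
        specs[a.gene_id], specs[b.gene_id] = a, b
        if mode == "tandem":
            c = next_chrom()
            spacer(c)
            chrom_lists[c] += [a.gene_id, b.gene_id]
        elif mode == "proximal":
            c = next_chrom()
            spacer(c)
            chrom_lists[c].append(a.gene_id)
            for _ in range(int(rng.integers(2, 8))):
                s = next(pool_iter, None)
                if s is not None:
                    chrom_lists[c].append(s.gene_id)
            chrom_lists[c].append(b.gene_id)
        elif mode == "dispersed":
            c1, c2 = next_chrom(), next_chrom()
            if c1 == c2:
                c2 = (c2 + 1) % config.n_chromosomes
            spacer(c1)
            chrom_lists[c1].append(a.gene_id)
            spacer(c2)
            chrom_lists[c2].append(b.gene_id)
        elif mode == "wgd":
            c1, c2 = next_chrom(), next_chrom()
            if c1 == c2:
                c2 = (c2 + 1) % config.n_chromosomes
            spacer(c1)
            spacer(c2)
            run_a, run_b = [], []
            og_slot = int(rng.integers(config.wgd_run_length))
            for k in range(config.wgd_run_length):
                if k == og_slot:
                    run_a.append(a.gene_id)
                    run_b.append(b.gene_id)
                else:
                    m = int(rng.integers(*config.pair_codons))
                    p_cds = _random_cds(rng, m)
                    q_cds = _mutate_to_ks(rng, p_cds, float(rng.uniform(*config.ks_range)))
                    p = _GeneSpec(new_id(), "anchor", p_cds, False, in_outgroup=True)
                    q = _GeneSpec(new_id(), "anchor", q_cds, False, in_outgroup=True)
                    p.partner, q.partner = q.gene_id, p.gene_id
                    specs[p.gene_id], specs[q.gene_id] = p, q
                    run_a.append(p.gene_id)
                    run_b.append(q.gene_id)
            chrom_lists[c1] += run_a
            chrom_lists[c2] += run_b
        elif mode == "transposed":
            # ancestral copy keeps its locus (outgroup carries it); the new
            # copy sits elsewhere with no outgroup counterpart
            a.in_outgroup = True
            c1, c2 = next_chrom(), next_chrom()
            if c1 == c2:
                c2 = (c2 + 1) % config.n_chromosomes
            spacer(c1)
            chrom_lists[c1].append(a.gene_id)
            spacer(c2)
            chrom_lists[c2].append(b.gene_id)
        else:
            raise ValueError(f"unknown duplication mode {mode!r}")

    for mode, count in sorted(config.duplication_plan.items()):
        for _ in range(count):
            plant_pair(mode)

    for i in range(config.te_gene_count):
        cds = orphan_cds(config.pair_codons)
        frag_len = max(60, int(0.6 * len(cds)) // 3 * 3)
        start = int(rng.integers(0, len(cds) - frag_len + 1))
        fragment = cds[start:start + frag_len]
        te_seq = _random_nt(rng, 150) + fragment + _random_nt(rng, 150)
        te_library.append((f"TE{i:03d}", te_seq))
        s = _GeneSpec(new_id(), "te", cds, True, origin_mode="te")
        specs[s.gene_id] = s
        c = next_chrom()
        spacer(c)
        chrom_lists[c].append(s.gene_id)
    # background TE records no gene derives from
    for j in range(5):
        te_library.append((f"TEbg{j:02d}", _random_nt(rng, int(rng.integers(300, 800)))))

    for cat, n_count in (("overlap", config.overlap_gene_count),
                         ("de_novo", config.denovo_gene_count),
                         ("plain_orphan", config.plain_orphan_count)):
        for _ in range(n_count):
            rng_len = config.pair_codons if cat != "plain_orphan" else config.orphan_codons
            s = _GeneSpec(new_id(), cat, orphan_cds(rng_len), True,
                          origin_mode=None if cat == "plain_orphan" else cat)
            if cat == "plain_orphan":
                s.origin_mode = "unclassified"
            specs[s.gene_id] = s
            c = next_chrom()
            spacer(c)
            chrom_lists[c].append(s.gene_id)

    # panel stages for every non-orphan
    stage_idx = np.arange(len(config.stage_names))
    for s in specs.values():
        if not s.is_orphan and s.stage is None:
            s.stage = config.stage_names[int(rng.choice(stage_idx, p=config.stage_probs))]
    # paired non-orphan anchors share a stage so the elimination stage is
    # exactly the planted one
    for s in specs.values():
        if s.category == "anchor" and s.partner:
            specs[s.partner].stage = s.stage

    # distribute leftover plains
    leftover = list(pool_iter)
    for i, s in enumerate(leftover):
        chrom_lists[i % config.n_chromosomes].append(s.gene_id)

    ordered_specs = [specs[g] for lst in chrom_lists for g in lst]
    return ordered_specs, te_library, chrom_lists


def _emit_genome(config, rng, specs, te_library, chrom_lists) -> GenomePackage:
    spec_by_id = {s.gene_id: s for s in specs}
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci, gene_ids in enumerate(chrom_lists):
        chrom = f"chr{ci + 1}"
        pos = 1
        chunks: list[str] = []
        for gid in gene_ids:
            s = spec_by_id[gid]
            gap = _random_nt(rng, int(rng.integers(200, 800)))
            chunks.append(gap)
            pos += len(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            pieces = _split_cds(rng, s.cds)
            genomic_pieces = (pieces if strand == "+"
                              else [reverse_complement(p) for p in reversed(pieces)])
            exons = []
            for k, piece in enumerate(genomic_pieces):
                if k > 0:
                    intron = _random_nt(rng, int(rng.integers(60, 180)))
                    chunks.append(intron)
                    pos += len(intron)
                exons.append((pos, pos + len(piece) - 1))
                chunks.append(piece)
                pos += len(piece)
            genes.append(GeneModel(
                gene_id=gid, chromosome=chrom, strand=strand,
                start=exons[0][0], end=exons[-1][1], exons=exons,
                cds_seq=s.cds, protein_seq=translate(s.cds)))
        chunks.append(_random_nt(rng, int(rng.integers(300, 600))))
        genome[chrom] = "".join(chunks)
    return GenomePackage(species_id="synthetic_focal", genome=genome,
                         genes=genes, te_library=te_library)


def _split_cds(rng, cds: str) -> list[str]:
    max_exons = max(1, min(4, len(cds) // 90))
    k = int(rng.integers(1, max_exons + 1))
    if k == 1:
        return [cds]
    cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=k - 1, replace=False))
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(cds[prev:int(c)])
        prev = int(c)
    pieces.append(cds[prev:])
    return pieces


# ---------------------------------------------------------------------------
# reference panel + origin context
# ---------------------------------------------------------------------------

def simulate_reference_panel(package: GenomePackage, truth: pd.DataFrame,
                             config: SimConfig) -> list[ReferenceDB]:
    """Build the ordered cascade panel for a simulated package.

    Every non-orphan gene receives one homolog (protein identity
    ``config.homolog_identity``) in the database of its planted stage;
    orphans appear nowhere. Each database also carries random decoy
    proteins so that searches against it are non-trivial.
    """
    rng = np.random.default_rng(config.seed + 1)
    proteins = dict(package.proteome())
    records: dict[str, list[tuple[str, str]]] = {n: [] for n in config.stage_names}
    for gid, row in truth.iterrows():
        if row.is_orphan or row.stage is None:
            continue
        hom = _mutate_protein(rng, proteins[gid], config.homolog_identity)
        records[row.stage].append((f"hom_{gid}", hom))
    panel = []
    for rank, name in enumerate(config.stage_names):
        for d in range(config.decoys_per_db):
            length = int(rng.integers(100, 400))
            aas = list("ACDEFGHIKLMNPQRSTVWY")
            decoy = "".join(rng.choice(aas, size=length))
            records[name].append((f"decoy_{name}_{d:03d}", decoy))
        panel.append(ReferenceDB(name=name, kind="protein",
                                 records=records[name], stage_rank=rank))
    return panel


def simulate_origin_context(package: GenomePackage, truth: pd.DataFrame,
                            config: SimConfig) -> tuple[OriginContext, GenomePackage]:
    """Other-species CDS database, partner genome (for de novo) and an
    outgroup package (for transposed classification)."""
    rng = np.random.default_rng(config.seed + 2)
    spec_rows = truth

    # overlap db: ~60 % fragments of each planted overlap OG, lightly mutated
    cds_records: list[tuple[str, str]] = []
    for gid, row in spec_rows[spec_rows.category == "overlap"].iterrows():
        cds = package.gene(gid).cds_seq
        frag_len = int(0.6 * len(cds))
        start = int(rng.integers(0, len(cds) - frag_len + 1))
        frag = _mutate_nt(rng, cds[start:start + frag_len], 0.05, keep_frame_open=False)
        cds_records.append((f"othercds_{gid}", frag))
    for j in range(20):
        cds_records.append((f"othercds_decoy{j:02d}",
                            _random_nt(rng, int(rng.integers(300, 1200)))))
    other_cds = ReferenceDB(name="other_species_cds", kind="nucleotide",
                            records=cds_records, stage_rank=0)

    # partner genome: de novo orthologous regions with premature stops
    partner_records: list[tuple[str, str]] = []
    for gid, row in spec_rows[spec_rows.category == "de_novo"].iterrows():
        cds = package.gene(gid).cds_seq
        region = list(_mutate_to_ks(rng, cds, 0.05))
        stop_codon = int(0.4 * (len(cds) // 3))
        region[3 * stop_codon:3 * stop_codon + 3] = "TAA"
        partner_records.append((f"partner_region_{gid}",
                                _random_nt(rng, 150) + "".join(region) + _random_nt(rng, 150)))
    for j in range(10):
        partner_records.append((f"partner_decoy{j:02d}",
                                _random_nt(rng, int(rng.integers(500, 1500)))))
    partner_genome = ReferenceDB(name="partner_genome", kind="nucleotide",
                                 records=partner_records, stage_rank=0)

    te_db = ReferenceDB(name="te_library", kind="nucleotide",
                        records=list(package.te_library), stage_rank=0)

    outgroup = _emit_outgroup(package, spec_rows, config, rng)
    context = OriginContext(other_cds=other_cds, te_library=te_db,
                            other_genomes=[partner_genome], outgroup=outgroup)
    return context, outgroup


def _emit_outgroup(package: GenomePackage, truth: pd.DataFrame,
                   config: SimConfig, rng: np.random.Generator) -> GenomePackage:
    """Outgroup species: ordered ~diverged copies of genes that sit at
    ancestral loci (plain genes, anchors, transposed ancestral copies)."""
    keep = set(truth[truth.category.isin(("nog", "anchor"))].gene_id)
    # ancestral member of each transposed pair = the first-created one
    for gid, row in truth[truth.category == "transposed"].iterrows():
        if row.partner and gid < row.partner:
            keep.add(gid)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in package.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, glist in sorted(by_chrom.items()):
        out_chrom = f"out_{chrom}"
        pos = 1
        chunks: list[str] = []
        for g in sorted(glist, key=lambda x: x.start):
            if g.gene_id not in keep:
                continue
            gap = _random_nt(rng, int(rng.integers(150, 400)))
            chunks.append(gap)
            pos += len(gap)
            cds = _mutate_nt(rng, g.cds_seq, config.outgroup_divergence)
            chunks.append(cds)
            genes.append(GeneModel(
                gene_id=f"out_{g.gene_id}", chromosome=out_chrom, strand="+",
                start=pos, end=pos + len(cds) - 1, exons=[(pos, pos + len(cds) - 1)],
                cds_seq=cds, protein_seq=translate(cds)))
            pos += len(cds)
        chunks.append(_random_nt(rng, 200))
        genome[out_chrom] = "".join(chunks)
    return GenomePackage(species_id="synthetic_outgroup", genome=genome, genes=genes)


def simulate_study(config: SimConfig) -> SimResult:
    """One call producing package, truth, panel and origin context."""
    package, truth = simulate_package(config)
    panel = simulate_reference_panel(package, truth, config)
    context, outgroup = simulate_origin_context(package, truth, config)
    return SimResult(package=package, truth=truth, panel=panel,
                     context=context, outgroup=outgroup)


# ---------------------------------------------------------------------------
# expression simulators
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + dispersion * mu^2); Poisson in the zero-dispersion limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(n_genes: int = 1000,
                    tissues: tuple[str, ...] = ("root", "leaf", "male_flower",
                                                "female_flower", "fruit"),
                    replicates: int = 3,
                    n_specific: int = 50,
                    specific_ratio: float = 20.0,
                    dispersion: float = 0.05,
                    n_silent: int = 20,
                    seed: int = 0) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Tissue-panel counts with planted tissue-specific and silent genes.

    Specific genes express ``specific_ratio`` times higher in one focal
    tissue; library sizes vary at most threefold; counts are negative
    binomial around the planted means.
    """
    if len(tissues) < 2 or replicates < 2:
        raise ValueError("need >= 2 tissues and >= 2 replicates")
    rng = np.random.default_rng(seed)
    gene_ids = [f"e{i:05d}" for i in range(n_genes)]
    lengths = rng.integers(300, 3000, size=n_genes).astype(float)
    base = rng.lognormal(mean=math.log(50.0), sigma=1.0, size=n_genes)
    means = np.tile(base[:, None], (1, len(tissues)))
    specific_idx = rng.choice(n_genes, size=n_specific + n_silent, replace=False)
    silent_idx = specific_idx[n_specific:]
    specific_idx = specific_idx[:n_specific]
    focal = rng.integers(0, len(tissues), size=n_specific)
    for i, t in zip(specific_idx, focal):
        means[i, :] = max(2.0, base[i] / specific_ratio)
        means[i, t] = max(2.0, base[i] / specific_ratio) * specific_ratio
    means[silent_idx, :] = 0.0

    sample_ids, design, cols = [], {}, []
    size_factors = rng.uniform(0.6, 1.8, size=len(tissues) * replicates)
    k = 0
    for t_i, t in enumerate(tissues):
        for r in range(replicates):
            sid = f"{t}_r{r + 1}"
            sample_ids.append(sid)
            design[sid] = t
            cols.append(_nb_draw(rng, means[:, t_i] * size_factors[k], dispersion))
            k += 1
    counts = np.column_stack(cols)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_specific": [i in set(specific_idx) for i in range(n_genes)],
        "specific_tissue": [tissues[focal[list(specific_idx).index(i)]]
                            if i in set(specific_idx) else None
                            for i in range(n_genes)],
        "is_silent": [i in set(silent_idx) for i in range(n_genes)],
    }).set_index("gene_id", drop=False)
    em = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                          counts=counts, gene_lengths=lengths, design=design)
    return em, truth


def simulate_de_counts(n_genes: int = 2000, n_de: int = 100,
                       log2fc: float = 3.0, replicates: int = 3,
                       de_base_mean: float = 500.0,
                       dispersion: float = 0.05,
                       seed: int = 0):
    """Two-condition counts with planted differential expression.

    Returns (counts, sample_groups, truth); DE genes sit at
    ``de_base_mean`` in the control condition and shift by ±``log2fc``
    (random sign) in the treatment; the rest are null.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"d{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=math.log(100.0), sigma=1.2, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    base[de_idx] = de_base_mean
    signs = rng.choice([-1.0, 1.0], size=n_de)
    mean_a = base.copy()
    mean_b = base.copy()
    mean_b[de_idx] = base[de_idx] * 2.0 ** (signs * log2fc)
    sf = rng.uniform(0.7, 1.5, size=2 * replicates)
    cols = []
    groups = []
    for r in range(replicates):
        cols.append(_nb_draw(rng, mean_a * sf[r], dispersion))
        groups.append("control")
    for r in range(replicates):
        cols.append(_nb_draw(rng, mean_b * sf[replicates + r], dispersion))
        groups.append("treated")
    counts = np.column_stack(cols)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_de": [i in set(de_idx) for i in range(n_genes)],
        "true_log2fc": [signs[list(de_idx).index(i)] * log2fc
                        if i in set(de_idx) else 0.0 for i in range(n_genes)],
    }).set_index("gene_id", drop=False)
    return counts, groups, truth


def simulate_trends(n_per_cluster: int = 100, n_stages: int = 6,
                    noise: float = 0.1, seed: int = 0):
    """Two well-separated trend groups (monotone up vs down) plus labels."""
    rng = np.random.default_rng(seed)
    up = np.linspace(-1.0, 1.0, n_stages)
    down = up[::-1]
    profiles = np.vstack([
        up[None, :] + rng.normal(0.0, noise, size=(n_per_cluster, n_stages)),
        down[None, :] + rng.normal(0.0, noise, size=(n_per_cluster, n_stages)),
    ])
    labels = np.array([0] * n_per_cluster + [1] * n_per_cluster)
    return profiles, labels


def simulate_module_blocks(block_sizes=(40, 40), n_samples: int = 12,
                           within_r: float = 0.9, seed: int = 0):
    """Orthogonal co-expression blocks: x = sqrt(r) * factor + sqrt(1-r) * noise."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(block_sizes):
        factor = rng.normal(size=n_samples)
        for _ in range(size):
            eps = rng.normal(size=n_samples)
            rows.append(math.sqrt(within_r) * factor + math.sqrt(1 - within_r) * eps)
            labels.append(b + 1)
    return np.vstack(rows), np.array(labels)
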