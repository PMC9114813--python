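# Methods

This note records the models, conventions and design choices behind
`orphanforge`, what the synthetic-data generator does and does not
emulate, and therefore what a passing test suite does and does not show
about real data.

## Orphan definition and the filter cascade

A gene is an orphan (OG) when its protein has no hit with
E ≤ 10⁻⁵ in any database of an ordered reference panel; the threshold is
inclusive at equality. The cascade queries only the survivors of each
stage at the next one, so the per-stage survivor counts are non-increasing
and the per-gene audit trail records the first eliminating stage. Because
elimination is "hit anywhere", the final OG set does not depend on panel
order — a property the suite tests directly. Records whose ID equals the
query's gene ID never eliminate (the panel describes *other* species and
databases; a stray copy of the query's own record must not disqualify it).

## Homology engine

The engine is a desk-scale stand-in for protein, nucleotide and
translated-protein search. Alignment is optimal local Smith–Waterman with
affine gaps; the dynamic programming core is `Bio.Align.PairwiseAligner`
(BLOSUM62, gap open 11 / extend 1 for protein scoring; +1/−2, open 5 /
extend 2 for nucleotide), verified in the test suite against an
independent brute-force Gotoh DP written from scratch. Candidate subjects
come from exact-word seeding: 3-mer two-hit on a shared diagonal (two
non-overlapping word hits within 40 positions) for protein, exact 11-mers
(single hit) for nucleotide. Protein candidates then pass an ungapped
diagonal extension filter (maximum-subarray of BLOSUM62 scores along the
triggering diagonals, threshold 45) before full DP. A pair with ungapped
identity ≥ 70 % over ≥ 50 columns scores ≥ ~140 ungapped, so the filter
cannot lose the homologs the cascade decisions rest on; this sensitivity
floor is tested.

E-values follow Karlin–Altschul, `E = K·m·n·e^(−λS)`, with fixed
per-scheme parameters (λ = 0.267, K = 0.041 gapped BLOSUM62; λ = 1.28,
K = 0.46 for +1/−2) and no edge-effect or length-adjustment correction.
This is a deliberate approximation: at desk scale the cascade makes
threshold decisions on planted strong versus absent homology, where the
correction terms are immaterial. No bit-compatibility with production
search tools is claimed; `hits_from_tabular` ingests 12-column tabular
hits so a production tool can be substituted at real scale.

Translated search scans all six frames, keeps stop codons as `*` (scored
by BLOSUM62's stop column, so an alignment can cross a single premature
stop at a −4 penalty, as in translated database search practice) and
reports subject spans in forward-strand nucleotide coordinates plus the
frame-local amino-acid span needed by the de novo rule.

## Structure statistics

GC content is computed on the CDS (the alternative, gene-body GC, can be
obtained from the genome sequence; the choice is recorded in the output
provenance). Exon length is the per-gene mean of genomic exon lengths;
protein length excludes the stop. Multi-isoform genes collapse to the
longest-CDS mRNA. The isoelectric point solves `charge(pH) = 0` by
bisection on [0, 14] with the EMBOSS pK set (N-term 8.6, C-term 3.6,
K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) to |charge| < 10⁻⁴.
Other pK tables shift absolute pI values slightly but leave OG-vs-NOG
contrasts intact, which is all the pipeline interprets.

Group contrasts use the two-sided Wilcoxon rank-sum test: exact
enumeration when the pooled sample is ≤ 10 and tie-free, otherwise the
normal approximation with midrank ties, tie-corrected variance and
continuity correction. The approximation's worst-case error against the
exact null over all two-group splits of ten distinct values is 0.0392
(reached at the 2-vs-8 split with U = 5, exact p = 0.400); the error is a
function of ranks only, so no choice of values improves it. The package
avoids the issue at small n by using enumeration there; the measured
bound is asserted in the unit suite.

"Near telomere" is defined as the outer 10 % of each chromosome arm; the
telomere-proximity summary is the ratio of mean per-window OG fraction in
terminal windows to the interior mean (infinite when all OGs are
terminal, undefined without informative windows).

## Origin classification

Mechanisms are tested in a fixed precedence order — duplication, overlap,
TE exaptation, de novo, unclassified — and each OG receives exactly one
label. The precedence mirrors the order in which the evidence is usually
gathered (within-genome paralogy first, cross-species nucleotide evidence
last) and is recorded here because a gene can satisfy several rules.

*Duplication.* Paralog pairs are reciprocal within-genome protein hits at
E ≤ 10⁻⁸, each gene keeping its best-bit-score partner. Collinear blocks
are maximal chains of anchor pairs, strictly monotone in gene rank on
both axes (either orientation), rank gaps ≤ 25, at least 5 anchors;
chains are extracted greedily by size, and chaining is verified against
an exhaustive oracle for small anchor sets. Mode precedence: WGD (pair is
an anchor pair of a block) > tandem (adjacent ranks, same chromosome) >
proximal (rank distance 2–10) > transposed (exactly one gene has a
collinear match in an outgroup genome — evaluated only when an outgroup
package is supplied; otherwise such pairs fall to dispersed) > dispersed.

*Ks dating.* CDSs are codon-aligned by back-threading a global protein
alignment; gap columns drop pairwise; codons with ambiguity or stops are
skipped. Site counts and pathway-averaged synonymous/nonsynonymous
differences follow NG86: mutations creating stops count as
nonsynonymous, minimal mutation pathways through stop codons are excluded
(equal weights over the remainder; if every pathway is blocked, all are
used). `Ks = −¾ ln(1 − 4/3·pS)`, undefined (flagged saturated) at
pS ≥ ¾. Ages are `T = Ks/(2μ)` in MYA with μ = 6.5 × 10⁻⁹ by default.
The estimator is checked against an independent pathway-enumeration
oracle to 10⁻⁹ and recovers planted Ks with median relative error < 1 %
at 200 codons (±20 % band tested across 0.1 ≤ Ks ≤ 0.8).

*Overlap.* Union coverage of the OG CDS by all nucleotide hits
(E ≤ 10⁻⁵) to other-species CDS must reach 50 %. Coverage merges query
spans across hits before dividing by CDS length.

*TE exaptation.* Any nucleotide hit (E ≤ 10⁻⁵) of the OG CDS against the
TE library. The TE library is an input; repeat discovery is out of scope.

*De novo.* Some other genome must contain a translated hit with identity
≥ 60 %, query coverage ≥ 80 % and E ≤ 10⁻⁶ whose hit-frame ORF
(translation from the alignment start to the first stop) is shorter than
half the orphan protein — an alignable but non-coding orthologous region.

## Expression inference

FPKM is `counts·10⁹ / (length_bp · library_size)`. "Expressed" means
FPKM > 0.02 in at least one sample (a mean-based rule is available by
flag). SPM is the cosine between a gene's tissue-mean vector and each
tissue's unit vector; SPM ≥ 0.9 calls the gene specific to its
maximal tissue. SPM is scale-invariant, so library-size effects cancel at
the profile level.

The DE screen is a deliberately lightweight, fully documented procedure:
median-of-ratios size factors; log₂ fold change of normalized group means
with pseudocount 1; a Wald test whose variance combines Poisson and
overdispersion terms, `Var(log FC) ≈ Σ_groups (1/μ + α)/(n·ln²2)`, with a
single pooled method-of-moments dispersion α (median of per-gene
moment estimates over genes with informative means); BH adjustment; DE
called at FDR < 0.05 and |log₂FC| > 1. Its calibration — empirical FDR
and power on planted truth — is what the tests assert; equality with any
particular heavyweight estimator is not claimed, and externally produced
DE tables can be supplied instead. With the pseudocount, planted
normalized means of 400 vs 1600 yield log₂FC 1.997; very low means are
shrunk toward zero, which is intended.

Fuzzy c-means follows Bezdek's alternating optimization with fuzzifier
m = 2 on per-gene z-standardized profiles, membership
`u_ij = 1/Σ_k (d_ij/d_kj)^{2/(m−1)}`, convergence at membership change
< 10⁻⁶, objective asserted non-increasing every iteration, bounded
re-seeding on degenerate duplicate centers. Genes with maximal membership
> 0.6 form the screened cluster sets.

Co-expression modules: adjacency `|r|^β` with β the smallest integer in
1..20 whose connectivity distribution fits a power law with R² ≥ 0.8
(fallback β = 6); topological-overlap similarity; average-linkage
clustering of 1 − TOM. The tree is cut inside the largest gap of the
merge-height sequence — a self-tuning rule that separates tight
within-module merges from the final between-module joins without a
hand-picked height (a fixed cut height proved fragile to the noise
realization and can merge well-separated modules); an explicit height can
still be passed. Clusters under 30 genes merge into the module whose
eigengene correlates with them at |r| > 0.5, else stay unassigned. The
module eigengene is the first right singular vector of the standardized
module expression (sign-aligned with the mean member profile) — it is the
unit-norm sample combination explaining the largest share of module
variance, which the suite verifies by eigendecomposition. Hub genes
require MM > 0.95 and |GS| > 0.85 against the module's best-correlated
trait. Enrichment is the upper-tail hypergeometric probability with BH
adjustment across terms, significant at p < 0.05.

## Synthetic data: what it emulates, what it does not

The generator builds a genome package (chromosome sequences, gene models
with 1–4 exons on random strands, TE library), an ordered four-stage
reference panel, an other-species CDS set, a partner genome for the
de novo rule and an outgroup package, all deterministically from one seed
(byte-identical reruns are tested and measured end to end).

Planted conditions, chosen once as the study conditions of the default
acceptance run: 1,000 genes on 4 chromosomes, 50 planted orphans — 3
duplicate pairs of each of the five modes (synonymous-site mutation of a
parent CDS to a target Ks drawn from 0.1–0.5, so Ka ≈ 0 — the dating
pipeline only consumes Ks), 5 TE-derived genes (≥ 60 % of the CDS present
in a TE-library record), 5 overlap cases (a ~60 % CDS fragment at ~95 %
nucleotide identity in the other-species CDS set), 5 de novo cases
(partner-genome region at high identity with an in-frame stop at 40 % of
the protein), 5 plain unclassifiable orphans. Non-orphans carry one
homolog at ~80 % protein identity in exactly one panel stage (stage drawn
with probabilities 0.70/0.15/0.10/0.05), so the elimination-stage audit
is decidable; each database also carries random decoy proteins. WGD
pairs sit inside planted runs of six collinear anchor pairs; events on
one chromosome are separated by ~30 background genes so no spurious
collinearity can arise. The outgroup contains ordered ~7 %-diverged
copies of genes at ancestral loci, omitting the novel copy of each
transposed pair. All panel stages are protein databases (the
transcript-assembly stage of a real panel is nucleotide; the cascade
decision is the same for a protein search against its translation).

Count matrices are negative binomial (`var = μ + αμ²`, Poisson at α = 0)
with lognormal baseline means, library-size factors within threefold,
dispersion 0.05; 50 of 1,000 genes are tissue-specific at 20× in one of
five tissues and 20 are silent. The DE simulator plants 100 of 2,000
genes at |log₂FC| = 3 around mean 500 with 3 replicates per condition.
Trend and module simulators generate monotone up/down profiles
(noise σ = 0.1 over 6 stages) and orthogonal 40-gene factor blocks
(within-block r = 0.9 over 12 samples).

Deliberate non-realism, hence limits of what green tests show: intergenic
and decoy sequence is i.i.d. uniform (no repeats, no composition bias);
homolog divergence is uniform substitution (no indels, no rate
heterogeneity); planted effect sizes are strong and well-separated. The
suite therefore demonstrates correctness of the decision rules and
calibration under the stated model, not performance on borderline
homology, saturated Ks, or weakly specific expression. Synthetic
divergence settings are extreme by design (homologs ≥ 70 % identity,
orphans random), which is exactly the regime where cascade precision and
recall of 1.0 are the correct expectation.

## Numerical conventions and degenerate inputs

1-based inclusive coordinates everywhere (half-open arithmetic is
localized); minus-strand CDS reverse-complemented before translation;
ambiguity codons translate to X; a trailing partial codon warns and is
ignored. Local alignments with no positive-scoring cell return "no hit".
Hit sorting ties break by (subject ID, query start). Saturated Ks and
all-zero expression profiles are flagged and excluded rather than forced.
Constant pooled samples give rank-sum p = 1; constant gene rows are
dropped (with a warning) before module detection; constant traits yield
undefined correlations, flagged. All stochastic operations take explicit
seeds; pipeline thresholds live in one `RunConfig` and are echoed into a
provenance header on every output file.

## Problem sizes

Defaults were sized for a single CPU: the full synthetic study (1,000
genes) runs the cascade in ~25 s and origin classification in ~2 min;
statistical calibration uses 20 DE simulations of 2,000 genes, 10
SPM/trend replicates and 3 module replicates. These sizes give planted
effects enough replication for the stated recovery bands while keeping a
complete end-to-end run in minutes.
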