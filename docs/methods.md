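# Methods

`paleoretain` reconstructs the comparative-genomics chain of evidence used
to study ancient polyploidy in plant families: collinear block detection,
Ks-based dating and ordering of whole-genome multiplications, calling of
regions that retained all post-polyploidy copies, statistics on their
composition and gene content, and synteny-based tracing of single-gene
losses. Because the real analyses run on multi-gigabase genomes and external
databases, every stage here is validated instead on simulated genomes whose
full event history is recorded, at sizes that run on a laptop.

## Divergence estimation (Ks/Ka)

Per-pair synonymous and nonsynonymous divergence uses Nei–Gojobori (1986)
counting: synonymous site counts are averaged over the two sequences, codon
pairs differing at several positions are resolved by averaging over minimal
substitution pathways (pathways through stop codons are excluded; any change
*to* a stop counts as nonsynonymous), and the Jukes–Cantor correction
`d = -(3/4) ln(1 - (4/3)p)` is applied separately to the synonymous and
nonsynonymous proportions. A proportion at or above 3/4 is flagged
saturated. This is a deliberate simplification relative to maximum-likelihood
codon models (e.g. codeml under F3x4): for locating and ordering Ks peaks the
method-of-moments estimator is sufficient, dependency-free, and exactly
checkable against a brute-force reimplementation (the test suite does this to
1e-9 on 500 random pairs).

Unequal-length pairs are aligned by globally aligning the translations
(BLOSUM62, gap open −10, extend −0.5 per additional residue) and mapping the
alignment back to codons; gapped columns are discarded before counting.

## The simulator and its codon alphabet

The simulator evolves a single-copy ancestor along a user-supplied species
tree. Structural events — whole-genome multiplication, fractionation, tandem
duplication, inversions/translocations, targeted gene loss — are applied at
configured ages on configured branches and appended to an event log from
which every tip's gene content, order, strands and coordinates can be
replayed exactly (sequence substitutions are logged as counts).

Coding sequences are restricted to the six fourfold-degenerate codon
families (Val, Ser4, Pro, Thr, Ala, Gly). Under this alphabet each codon has
exactly one synonymous site (the third position) on which substitution is a
4-state symmetric process, and two nonsynonymous sites; amino-acid changes
move between families that differ by one first- or second-position
nucleotide, so stop codons can never arise. The payoff is exactness: the true
pairwise Ks of two sequences separated by total branch time `t` is
`syn_rate * t` by construction, and NG86+JC is a consistent estimator of it
— the estimator-consistency benchmark (200 pairs, 300 codons, true Ks 0.2 /
0.5 / 1.0) recovers the truth within 5 % (typically < 2 %). The cost is that
amino-acid composition is unrealistic; none of the tested inferences depend
on it.

Key generator defaults (time unit = million years, Myr):

| parameter | default | meaning |
|---|---|---|
| `syn_rate` | 5e-3 /site/Myr | synonymous clock; Ks = 2·r·T |
| `nonsyn_factor` | 0.2 | amino-acid rate relative to synonymous (purifying) |
| `wg_multiplicity` | 3 | triplication |
| `retention_prob` | 0.5 | per-extra-copy survival of fractionation |
| `retention_bias` | cellwall ×1.3, fattyacid ×1.6 | label-biased retention |
| `retained_run_frac` / `retained_run_len` | 0.15, 30–60 genes | designated runs where all copies survive |
| `tandem_rate` | 0.02 /gene/branch | expected tandem duplications |
| `inversion_sizes` | 20–30 genes | micro-inversion size range |
| `gene_spacing` | 12 kb | gene starts; ~0.4–0.7 Mb designated runs |
| `repeat_base_frac` | 0.55 | repeat fraction of intergenic gaps |
| `repeat_depletion` | 0.5 | survival probability of LTR-RT elements in retained runs |

The canonical trio scenario places an old triplication at 150 Mya on the
stem above the root, a speciation of the outgroup at 85 Mya, a young
triplication at 80 Mya on the ingroup stem ("shortly after" the split:
ortholog peak 0.85 vs paralog peak 0.80), an ingroup split at 70 Mya, a
targeted single-gene loss at the border of a micro-inversion at 82 Mya on
the ingroup stem, and tandem bursts on the terminal branches.

Designated retained runs deserve a note. With purely independent per-copy
retention at p = 0.5, runs of three consecutive fully-triplicated genes occur
at rate ~p⁶ ≈ 1.6 % — too sparse to reproduce the megabase-scale retained
regions whose composition the downstream statistics compare. The simulator
therefore designates contiguous ancestral runs (dosage-sensitive clusters)
inside which every copy survives; repeat density around them is depleted by
preferential removal of whole LTR-RT elements. Independent per-family
retention still governs everything outside the runs, and the binomial
`p²` law for fully-retained families is preserved (and tested) when run
designation is disabled.

## Synteny

Anchors are same-family gene pairs (weight 1, or an externally supplied
similarity score), optionally capped per gene. Chaining works in gene-rank
coordinates, maximising `Σ weights − gap_penalty · Σ skipped genes` by
O(n²) dynamic programming per chromosome pair, separately for the two
orientations, extracting chains greedily (each anchor joins one chain per
orientation pass). Defaults: `min_block_anchors` 5, `max_gap_genes` 25,
`gap_penalty` 0.2 per skipped gene; equal-score ties resolve by smaller
ranks so output is deterministic. The DP is validated against exhaustive
enumeration over all monotone anchor subsets on small instances.

Best-k layouts assign each reference gene the k highest-scoring blocks
covering its rank and flag whether the gene itself is anchored in each;
syntenic depth is the row sum. With k = 3 and a diploid reference this
reproduces per-gene post-triplication copy number exactly on noiseless
simulations.

## Retained regions (TRR calling) and composition

A retained region is a maximal run of reference genes with depth ≥
`min_copies`, tolerating up to `max_gap` consecutive sub-threshold genes
inside the run (runs begin and end on qualifying genes; `min_run` counts
qualifying genes). The paper-style definition never states a run length or
gap tolerance, so both are configuration with defaults `min_run 3`,
`max_gap 1`. Regions are mapped back to the target genome through the
anchors of the overlapping blocks, and windows are assigned to
region/background by majority overlap.

Composition per window counts genic and repeat bp once each (interval
unions). The region-vs-background comparison is a pooled-variance two-tailed
Student's t test (Welch behind a flag). Category enrichment uses the exact
hypergeometric tails — both enrichment (upper) and depletion (lower) are
computed and the smaller is reported with its direction — with
Benjamini–Hochberg control and a default adjusted threshold of 0.01. The
benchmark genome is two orders of magnitude shorter than a real plant
genome, so the composition experiment uses 0.5-Mb windows to keep ≥ 50
windows per genome; the windowing operation itself accepts any width/step.

## Event classification

Paralog Ks distributions are summarised by Gaussian mixtures on log-Ks
(range 0.01–3.0 by default, suppressing allelic noise and saturation),
component count chosen by minimum BIC with ties to fewer components,
deterministic given a seed. Peaks agreeing within 0.25 log-Ks across species
are clustered; a cluster whose species set equals a clade is assigned to
that clade's stem branch. Ordering against speciation compares the cluster
peak with the *smallest substantial* component of the relevant ortholog
distribution — cross-species syntelog pairs can predate the split
(paleo-homeologs) but not postdate it, so the youngest ortholog component
is the speciation peak. Separations below 0.02 Ks are reported as
"indistinguishable" rather than ordered. Multiplicity is read from the modal
syntenic depth near the peak when depth tracks are supplied.

## Loss tracing

A family's expected target locus is interpolated (linearly in rank) between
the nearest flanking anchors of a block covering its reference copy.
Inversions are detected as maximal anchor runs moving against the block's
consensus orientation, with relative-strand flips as corroborating (not
required) evidence and a 3-anchor minimum to avoid single-anchor noise.
Because a post-polyploidy genome maps a reference locus into several
homeologous regions and the scar need only exist on the homeolog that
carried the lost copy, `trace_family_loss` examines every covering block,
scanning a ±40-gene window around the locus, and classifies by the closest
breakpoint. A loss candidate with a breakpoint within `border_tolerance`
(default 2) genes of the expected interval is `lost_at_inversion_border`;
otherwise `lost`. On 100 noiseless replicates (50 border losses of 20–30
genes, 50 plain deletions) classification is ≥ 95 % accurate with exact
breakpoints.

## Family dynamics

Per-family clade expansion uses the pooled-variance two-tailed Student's t
test on per-species counts, flagged at p < 0.01 / 0.001 / 0.0001;
zero-variance families are reported "not testable" rather than p = 0.
Duplicate pairs are classified tandem (same chromosome, ≤ 10 intervening
genes — a common convention, configurable), WGD/segmental (the pair is
itself an anchor of an intra-genome block), else dispersed. Selection is
summarised as the Ka/Ks distribution and the purifying fraction (ratio < 1),
with Ks = 0 and saturated pairs reported separately. Low-copy-number
ortholog selection requires exactly one copy in every required species and
in at least m other species (boundary inclusive).

## Pipeline and determinism

`run_pipeline` executes synteny → Ks → peak models/event classification →
retained regions → composition/enrichment → loss tracing → family dynamics
from one YAML configuration, echoes every parameter into a manifest with
SHA-256 checksums of all outputs, and is bit-reproducible for a fixed
configuration and seed (all randomness flows from one generator; all
iteration orders are sorted). A failed stage halts the run, retains partial
outputs and writes a FAILED marker; a dataset without coding sequences skips
the Ks-dependent stages with a logged reason. The three-taxon demo cannot
run the clade-vs-rest expansion t test (it needs two species per group), so
that stage step is skipped there with a logged reason; the test suite
exercises it on multi-species count tables.

## Problem sizes

Benchmarks use 200–2000 ancestral genes (up to ~10 000 genes per polyploid
tip), 300-codon coding sequences, and 100 loss replicates of 200 genes —
sizes chosen so the full validation runs in minutes while leaving every
statistic well-powered (e.g. > 20 000 paralog pairs behind each mixture
fit).

## Known limitations

- NG86+JC underestimates Ks for strongly saturated pairs; values with
  synonymous proportion ≥ 3/4 are flagged and excluded rather than rescued.
- The simulator does not model intergenic sequence, recombination,
  nucleotide-level repeat sequence, or rate variation among lineages;
  passing benchmarks demonstrate correctness of the inference machinery, not
  robustness to real-data noise such as annotation error or alignment
  ambiguity.
- Anchor discovery is family-based; protein-similarity anchor scoring must
  be supplied externally.
- Event ordering relies on peak positions only; it cannot resolve events
  closer than the configured minimum separation (0.02 Ks).
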