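# Methods

This note documents the models and procedures implemented in `epiguide`,
the parameters that matter, the choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Library design

### Sequence conventions

A candidate guide is a 20-nt protospacer whose genomic site is immediately
followed by an NGG PAM. Internally every candidate carries a 30-nt scoring
context — 4 nt upstream + protospacer + 3-nt PAM + 3 nt downstream, in
protospacer orientation — and a 23-mer (protospacer + PAM) used for the
off-target search. This 30-mer layout is the convention of the widely used
on-target efficiency regressors, which is why it is the context handed to
any plugged-in scorer. Coordinates are 0-based half-open throughout; BED is
read natively, GTF is converted on input (and never written).

Candidate enumeration scans both strands of each domain interval. The
23-mer must lie fully inside the interval (intervals shorter than 23 nt
yield no candidates, not an error); the 30-nt context may extend into the
flanking chromosome and a candidate is excluded only when that context runs
off a chromosome end or contains N.

### Low-complexity exclusion

Published domain-library designs trim low-complexity sequence before guide
extraction without specifying the masker. We use the simplest deterministic
surrogate: a candidate is excluded when its protospacer overlaps a
homopolymer run of at least `lowcomplexity_min_run` bases (default 8). The
threshold is configurable; 8 is long enough that ordinary sequence almost
never triggers it while genuine homopolymer stretches always do.

### The 5′ G

U6-driven sgRNAs start with G. Two policies are offered: the default
requires a *genomic* G at protospacer position 1 (no sequence alteration —
the stricter reading of "a unique sgRNA sequence of 20 nt length starting
with a G"), and a substitution mode keeps non-G candidates and substitutes
the first base to G in the synthesized oligo only, leaving the genomic
23-mer used for off-target search untouched. Control guides supplied as
bare sequences (non-targeting, positive controls) are always G-substituted
when needed, since they have no genomic design site to preserve.

### On-target scoring

Trained on-target efficiency models are regressors over the 30-nt context;
re-training one is out of scope here. The bundled
`PositionWeightScorer` is a deterministic surrogate — a logistic squash of
summed per-(position, base) weights — documented as a stand-in, with mild
default weights (reward G adjacent to the PAM, moderate seed GC). Scores
from any external model can be supplied per context via
`PrecomputedScorer.from_tsv`, and the whole scorer is configurable through
`DesignConfig.on_target_scorer`. All ranking logic depends only on a score
in [0, 1], so swapping scorers changes no other behaviour.

### Ranking and selection

Per gene, seven component rankings are computed: on-target score
descending; exonic off-target count, exonic max CFD, intronic count,
intronic max CFD, intergenic count, intergenic max CFD, each ascending.
Ties receive average (fractional) ranks — the standard mid-rank convention,
chosen because it is permutation-invariant and keeps the mean rank score
within [1, n]. The rank score is the arithmetic mean of the seven
components. Output order is ascending rank score with deterministic
tie-breaks (higher on-target score, then lexicographic protospacer), so a
re-run is byte-identical. Selection sorts candidates by (domain-category
priority, rank score) and keeps the top *k* (default 11; genes with fewer
candidates keep them all). The default category priority is catalytic >
reader > dna_binding > protein_interaction > other; only the first three
categories are canonical in the field, so the order of the remaining two is
a configuration default, not a claim.

### Oligos

Each selected guide becomes a 60-nt synthesis oligo: 20-nt left arm +
sgRNA + 20-nt right arm. Both default arms carry a BsmBI recognition site
(CGTCTC, on the minus strand in the left arm) so Golden-Gate digestion
releases the guide; arms are configurable but validated for length and for
the site on either strand. Library assembly refuses duplicate protospacers
anywhere in the union of targeting, non-targeting and positive-control
guides.

## Off-target search and CFD scoring

Mismatches are counted over the full 23-mer, mirroring end-to-end alignment
of the guide+PAM query; PAM-degenerate sites therefore appear as mismatched
hits rather than being invisible. The search is a pigeonhole
seed-and-extend: the query is split into four disjoint segments (6/6/6/5
nt); with at most 3 mismatches at least one segment must match exactly, so
exact lookups of each segment in a genome k-mer index enumerate a complete
candidate set, which is verified by direct Hamming comparison. A single
longer seed would be faster but incomplete (three mismatches can straddle
any one seed); completeness was preferred, and equivalence to an exhaustive
scan is enforced by the brute-force oracle tests. Genome-scale performance
engineering is explicitly out of scope.

Hits are reported in deterministic genomic order and truncated at
`max_reported` (35). Guides are dropped when they have more than one exact
genomic match (duplicated regions) or more than 25 alignments; because the
drop threshold (25) is below the truncation limit (35), truncation can
never change a keep/drop decision. For kept guides the on-target site —
identified by coordinates, or else as the unique exact match — is removed
before scorecard construction. Context classification is a partition:
exonic if the hit overlaps any exon on either strand, else intronic if
within a transcript span, else intergenic.

CFD scoring is the standard multiplicative model: one penalty per
mismatched protospacer position keyed by (position 1–20, guide base,
target base), times a PAM-dinucleotide penalty; matched positions
contribute 1, so identical sequences with a canonical GG PAM score exactly
1. The bundled tables
(`resources/cfd_synthetic_mismatch.tsv`, `cfd_synthetic_pam.tsv`) are
**synthetic**: a deterministic heuristic (PAM-distal mismatches more
tolerated; transversions penalized ~2× more than transitions; non-GG PAMs
strongly penalized). They preserve the model's structure for testing and
demonstration but are not measured cleavage frequencies; real published
tables load through the same TSV interface.

## Screen analysis

The analysis follows the classic dropout recipe, in this order:

1. **Counting** (when starting from FASTQ): a read's 20-nt guide region
   (configurable offset, default 0) is assigned to a library guide allowing
   at most one mismatch; reads matching more than one guide at their best
   stratum are discarded. This mirrors unique best-stratum short-read
   mapping of guide sequences.
2. **Normalization**: each sample divided by its own mean count, so
   per-sample means are exactly 1 and sequencing depth cancels.
3. **Low-abundance filter**: a guide is removed when its value in *any*
   reference-timepoint sample is ≤ the nearest-rank 2nd percentile of that
   sample. Nearest-rank was chosen because it is exact on small samples and
   has no interpolation ambiguity. A degenerate all-tied sample contributes
   no removals (the ≤ rule would otherwise remove everything).
4. **Fold changes**: normalized counts are averaged across the two
   biological replicates first, then fc = (mean later + ε)/(mean reference
   + ε). The reference timepoint is configurable and defaults to day 1
   (the screen's first sampled point; some descriptions call the same
   sample "day 0").
5. **Hit calling**: a guide is depleted when fc at day 11 ≤ 1/10 (boundary
   inclusive); a gene is a hit when at least one guide is depleted. The
   hit table reports each gene's minimum fold change and depleted-guide
   count, most-depleted first.

**Pseudocount.** ε defaults to half a read, the usual zero-count guard, and
is configurable (including 0). Because normalization maps samples onto mean
1, `run_screen_pipeline` converts the read-unit ε onto the normalized scale
by dividing by the mean raw reference depth; at depth 300 that is ~0.0017,
negligible except exactly where it matters (guides falling to zero).
Applying 0.5 directly on the normalized scale would be half the average
guide abundance and would clamp all fold changes near 0.5 — a scale error,
not a parameter choice. `compute_fold_changes` itself is scale-agnostic and
adds whatever ε it is given. One consequence: exact invariance of fold
changes under rescaling a sample's counts holds exactly at ε = 0 and to
O(ε/depth) otherwise.

**Auxiliary rules.** Gene-set comparison reports pairwise overlaps and all
Venn regions (cardinalities partition the union). Dependency
classification takes per-gene score lists, computes the median and calls a
gene common-essential iff median < −0.5 (strict). The high-confidence peak
filter keeps 100 ≤ wild-type reads ≤ 5000 and wild-type fold change > 1,
and is idempotent. Competition normalization divides each GFP+ trajectory
by its day-0 value and by the negative control's relative trajectory, so
every series starts at 1.

## Synthetic data: what it emulates and what it does not

`generate_toy_reference` emulates the *inputs* of the design stage: a
single-chromosome genome of non-overlapping, plus-strand, single-exon genes
with domain intervals inside them, ~50% GC, and a guaranteed minimum of NGG
sites per domain (domains are redrawn until the guarantee holds; an error
is raised if the domain length cannot host the requested sites). Category
labels are drawn from configurable probabilities whose default
(0.35/0.15/0.27/0.13/0.10 for catalytic/reader/dna_binding/
protein_interaction/other) mirrors the composition reported for real
domain-focused libraries. It does not emulate splice structure, repeats,
pseudogenes, or minus-strand genes — so passing design tests show the
pipeline's logic is correct, not that real-genome edge cases (e.g.
repeat-dense loci saturating the off-target filter) are handled gracefully
at scale.

`simulate_screen` emulates the *count structure* of a pooled dropout
screen: log-normal baseline abundances (μ=0, σ=1 — the typical skew of
synthesized libraries), geometric per-doubling decay for planted genes
(fitness^doublings, with timepoints day 1/7/11 at 0/10/15 population
doublings and 2 replicates), per-guide efficacy ~ Beta(5, 1) (most guides
effective, a tail of poor cutters), and negative-binomial noise with
dispersion α = 0.1 around depth-scaled expectations (default 300
reads/guide — a comfortable coverage for a small library; real screens at
1000× representation are deeper still). Defaults place 20 positive-control
genes and ~10% non-targeting guides, as in real library designs. It does
not model infection statistics (MOI), PCR jackpotting, guide-level
off-target toxicity, or replicate-specific batch effects; recovery numbers
from these simulations therefore measure the analysis rule's behaviour
under its own generative assumptions, not real-screen performance.

A wrinkle worth knowing: because sequencing depth is fixed per sample,
depleting guides shrink the pool and *inflate* every other guide's
normalized abundance at later timepoints (by ~20–25% when a quarter of the
library carries 16-fold effects). Measured fold changes of depleted guides
are correspondingly slightly above their raw fitness ratio, and
non-targeting medians sit slightly above 1 in effect-laden screens. This is
a real phenomenon of pooled screens, reproduced on purpose.

## Numerical and degenerate-input choices

- Ranking uses average ranks (`scipy.stats.rankdata`), with final ordering
  tie-broken deterministically; all pipeline outputs are byte-stable under
  re-runs with the same inputs and seed.
- Negative-binomial draws use (n = 1/α, p = n/(n+μ)); α ≤ 1e-9 falls back
  to Poisson (the α → 0 limit).
- Nearest-rank percentile: the ⌈p/100·n⌉-th smallest value; removal uses ≤.
- All-zero samples are an error in normalization (named per sample);
  all-tied reference samples remove nothing in the percentile filter.
- Seeds are mandatory for every stochastic operation; no global RNG state
  is used or mutated.
- Writers are atomic (temp-then-rename), so failed runs leave no partial
  output files.

## Problem sizes in the bundled checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data
at desk scale, chosen as the smallest sizes at which each property is
meaningfully exercised: off-target oracle equivalence on five 50-kb genomes
× 20 guides; rank-aggregation oracle on 100 random scorecard sets of 3–30
guides; screen calibration and recovery on 200 genes × 10 guides at depth
300 over 5 seeds (50 planted essential genes at 16-fold for recovery; none
for the null); end-to-end design on 8–12 gene toy references. Real
headline screen results depend on deposited sequencing data and are not
reproducible at this scale; what the checks establish is that every rule
of the procedure is implemented exactly (oracle equivalence, truth tables)
and that the pipeline is well calibrated under its stated generative model.

## Known limitations

- The off-target search is exact but in-memory and unoptimized; it is
  meant for toy genomes and method development, not mammalian-genome
  production runs.
- The bundled CFD and on-target tables are synthetic stand-ins; absolute
  guide scores are not biologically meaningful until real tables/models
  are supplied.
- Gapped (bulge) off-targets and alternative PAMs are not modelled.
- Hit calling is the plain fold-change rule by design; no per-gene
  statistical testing (MAGeCK-style), copy-number correction, or guide
  efficiency re-estimation from screen data.
- The GTF reader is minimal (transcript/exon features with quoted
  gene_id/transcript_id attributes), sufficient for standard annotations
  but not a general GFF3 parser.
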