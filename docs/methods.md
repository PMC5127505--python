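# Methods

`tlscan` analyses a pooled saturation-mutagenesis ("deep mutational
scanning") screen of a short essential coding region — modelled on the RNA
polymerase II trigger loop, Rpb1 residues 1076–1106 — and ships a
synthetic-data generator that emulates the screen end to end, so every
stage is testable without sequencing data.

## The screen model

A library of programmed single-codon substitution variants is transformed
into yeast, and pools are replica-plated onto a control medium (the
transformed pool, SC-Leu), a plasmid-shuffle medium (5FOA, removing the
wild-type copy), and a panel of 14 selective/stress conditions.  Each pool
is amplicon-sequenced.  The analysis proceeds in five stages:

1. **simulate** — generate the screen (only for synthetic runs);
2. **call** — merge read pairs, align codon-wise, call variants against
   the expected codon set;
3. **score** — allele frequencies, filters, log-ratio scores, replicate
   medians;
4. **qc** — spike-in template-switching estimate, replicate correlations;
5. **cluster** — mutant-class discovery from the phenotype profiles.

## Variant calling

Read pairs are merged requiring exact agreement of the mates in their
overlap, and the flanking sequences adjacent to the coding region (15 nt
per side by default; a config knob) must match the wild-type reference
exactly.  The core between the flanks is aligned to the reference with a
codon-unit global dynamic program: a diagonal move consumes one reference
codon and three read nucleotides and scores `codon_match` (+1) on exact
identity or `codon_mismatch` (−1) on any within-codon difference;
insertions and deletions of 1–3 nucleotides cost a constant `indel` (−2)
regardless of length.  The rationale for the defaults is that
a codon substitution must outscore the indel pair that could mimic it, so
substitution calls are canonical; all three scores are configurable.  Ties
in the traceback resolve deterministically: substitution over indel,
deletion over insertion, longer indels first.

For equal-length cores with at most `floor(2·indel/(mismatch−match))`
mismatched codons (2 under the defaults), the plain diagonal alignment is
provably optimal — equal lengths force any indel-bearing alignment to
contain at least two indel moves — and the aligner short-circuits to it.
The full DP is exact and unbanded; only the *input* length difference is
banded (±9 nt by default), beyond which a read is `unalignable`.

A mismatched codon is accepted only if it is one of the codons programmed
into the library at that position (or a spike-in codon); any other codon is
the signature of a sequencing error and rejects the read
(`unexpected_codon`), as does any indel (the programmed library contains
substitutions only).  Accepted reads with one substitution are singles,
with several are multiples (e.g. spike-in-derived doubles); all rejections
are tallied by reason so that accepted + rejected reconstructs the input
read count exactly.

## Scoring

With `f` denoting the fraction of mapped (accepted) reads, the phenotypic
score of a variant under a condition is

    score = log2(f_mut,sel / f_mut,unsel) − log2(f_wt,sel / f_wt,unsel)

where the unselected sample is the transformed pool of the same replicate.
The same statistic on control media (SC-Leu heterozygous, 5FOA shuffled)
is called the fitness score.  The log base (2) is configurable.

Zeros: a pseudocount of 0.5 is added to **all four counts of a cell, but
only in cells where at least one count is zero**.  An unconditional
pseudocount would break the exact depth-invariance of the score
(multiplying all counts in a sample by a constant must leave every score
unchanged — a property we hold as an invariant and test); the conditional
form keeps scores finite for fully depleted variants without perturbing
any cell that has data.

Filters follow the screen's two rules: a variant with fewer than 200 reads
in the transformed pool (summed over the pool replicates — a single
per-variant number, so a failing variant is dropped entirely) is excluded,
and a (variant, condition, replicate) cell is masked when **both** the
selected and unselected counts are below 50.  The literal both-below
reading is the default; the stricter either-side rule is a config option.
Replicates (three by default) are aggregated by the median over unmasked
replicate scores; a cell with no unmasked replicate is reported NA.

Lethality: a fitness-score threshold is calibrated on known viable and
lethal variants (163 and 16 in the original design) by minimising the
balanced misclassification error over candidate cutpoints (midpoints of
consecutive distinct calibration scores; ties resolve to the midpoint of
the optimal interval).  Balanced error weights the classes equally so the
10:1 imbalance cannot swamp the lethal side.  A score strictly below the
threshold is `predicted_lethal`.

## QC

Five excluded single variants are spiked into the pool as controls
(H1085Y, H1085Q, F1086S, G1097D, E1103G).  Doubles combining two spike-ins
cannot come from the library, so for every spike-in pair at distinct
residues (9 pairs: the two H1085 variants share a position) the ratio

    R = Freq(double) / (Freq(single1) · Freq(single2))

estimates template switching; frequencies are taken from the same sample
(default: the unselected transformed pool), and the pairs are averaged.
Comparing mean ratios between standard and emulsion PCR as a linear ratio
of means gives the fold suppression achieved by emulsion amplification.
Replicate reproducibility is pairwise Pearson correlation of per-variant
frequencies (pairwise-complete; constant vectors give NA).

## Mutant-class discovery

Variant profiles across conditions are compared by centred-correlation
distance, 1 − Pearson r over jointly measured conditions
(pairwise-complete, the convention of expression-clustering tools), and
clustered agglomeratively with average linkage (configurable).  Variants
whose distance to the rest is undefined (constant profile or fewer than
two shared conditions) are excluded with a warning.

The number of classes is an output: every distinct cut height of the
dendrogram defines a candidate partition; clusters holding less than 5% of
the clustered variants are collapsed to "unassigned" debris; among
candidates with 2–8 substantive classes, the partition with the highest
mean silhouette width wins, where debris variants contribute a silhouette
of zero (the singleton convention).  The debris rule exists because
variants with no coherent phenotype have correlation distance ≈ 1 to
everything and therefore detach at the very top of the tree; a plain
`maxclust` cut spends every extra cluster peeling such outliers one by one
and can never isolate the annotated major classes, while scoring only
cluster members would reward degenerate low cuts that discard most of the
data.  Spike-in anchors *name* the classes — loss-of-function spike-ins
mark Class 1 and gain-of-function spike-ins Class 3 — but never move a
variant; anchor consistency is recorded.

Class-versus-class condition contrasts use the classical pooled-variance
two-tailed unpaired t-test.  Two residue-level analyses are included:
per-bin transcription-start-site fraction changes relative to wild type
(six ordered bins summing to 1), and a least-squares regression of a
condition score (typically MPA) on the helical-propensity change of
tip-region substitutions (residues 1090–1096 by default, with an optional
residue exclusion, e.g. V1094).  The propensity scale is a replaceable
input table; the packaged `EXAMPLE_HELIX_PROPENSITY` is an example in the
style of published host-guest scales, not a result of this package.

## The synthetic screen

The generator's defaults are the package's study conditions:

- **Reference**: 31 codons, residues 1076–1106.  The nucleotide sequence is
  a deterministic back-translation of an amino-acid string that places the
  residues named in the mutational literature at their positions and
  arbitrary-but-fixed residues elsewhere; it is not genomic sequence and is
  fully overridable (FASTA + numbering offset).
- **Library**: one mutant codon per (position, alternative amino acid),
  chosen to maximise Hamming distance from the WT codon; excluded variants
  (default: the five spike-ins) are absent from synthesis; spike-ins enter
  at 0.005 each; wild type holds 0.10 of the pool; the remaining mass is
  split uniformly (or by a symmetric Dirichlet).  `n_variants` subsamples
  the library (412 by default) to emulate the set reaching analysis.
- **Selection**: a selected sample's frequencies are proportional to
  pool_fraction × 2^effect with the WT effect fixed at 0, drawn
  multinomially at 1e5 reads/sample (three replicates).  True effects are
  class-structured: three planted classes (35% / 25% / 35%) plus 5%
  neutral variants, per-variant Gaussian noise sd 0.3 log2 units around
  the class means.  Class means carry only signs the screen reports —
  all classes Gal^R (Class 1 strongly); Class 1 formamide-hypersensitive,
  slightly MPA-resistant, Mn-resistant; Class 2 formamide-resistant and
  otherwise quiet; Class 3 Spt^-, MPA^S and Mn/caffeine/cycloheximide-
  hypersensitive — at magnitude 2 for signature phenotypes.  Weakly
  allele-specific media (NaCl, ethanol, HCl, benomyl, NaOH, hydroxyurea)
  are neutral for every class.
- **Reads**: each read pair spans both flanks and the full coding region;
  per-nucleotide substitution errors at 1e-3 apply to the whole amplicon
  (template-level, so mates agree); no indel errors are generated (indels
  exist only as alignment events).  Template switching: with probability
  0.01 per read (divided by 2.5 in emulsion mode) the read is a
  single-crossover recombinant of two independently drawn pool molecules —
  when both are single variants at distinct codons the crossover falls
  between the mutated codons and the chimera is the double mutant.  The
  QC experiments use prominent settings (spike fraction 0.02, switch rate
  0.05, 1e6 reads) so double-mutant counts are measurable at desk scale.

What the generator does **not** emulate: PCR-cycle-level amplification
bias, per-mate independent sequencing errors, quality-score structure,
indel sequencing errors, colony-growth competition, and real biological
replicate variation beyond multinomial resampling.  Passing tests
therefore demonstrate the correctness and calibration of the analysis
under this generative model, not the error structure of any particular
sequencing run.

## Problem sizes and numerics

The delivered analyses run the screen at 412 variants × 14 conditions ×
3 replicates × 1e5 reads/sample (the full analysis takes a few minutes on
one CPU), 1e6 reads for the template-switching experiments, and 2000
simulations for the t-test calibration.  At this depth a library variant
holds ≈ 210 pool reads, so the 200-read pool filter is active at the
margin and scores carry ≈ 0.1–0.2 log2 units of counting noise per
replicate; the median over three replicates recovers planted effects with
mean absolute error well under 0.3 log2 units for variants at pool
fraction ≥ 1e-3.  All randomness flows from explicit integer seeds
(per-stage seeds are derived from the global seed by hashing the stage
name), FASTQ output order is sorted, and reruns are byte-identical —
determinism is asserted in the test suite.

Known limitations: multi-substitution variants beyond spike-in doubles are
tallied but not analysed; the lethality threshold is one-dimensional (the
5FOA fitness axis); silhouette-based class counting is a reproducible
surrogate for the manual cluster annotation of the original heatmaps and
is validated on simulation, not claimed to reproduce any hand-drawn
boundary.
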