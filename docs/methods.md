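# Methods

This note documents the models, algorithms and numerical choices behind
`protoselect`, what the synthetic-data generator does and does not emulate,
and the limitations that follow.

## Genome quality filtering

A genome is retained when its sequencing coverage is strictly above 30-fold
and it has strictly fewer than 100 contigs; boundary genomes (exactly 30×,
exactly 100 contigs) are rejected, reading "higher than" and "less than"
literally.  Missing coverage metadata is an error rather than a silent pass
or fail.  N50 is the length of the smallest contig in the descending-sorted
prefix whose cumulative length first reaches half the assembly.  The filter
deliberately does not estimate completeness or contamination from marker
genes (CheckM-style); coverage and contig count are the only criteria.

## Fragment-based ANI

ANI between two genomes is computed ANIb-style.  The query is chopped into
non-overlapping 1,000 bp fragments per contig (a trailing fragment shorter
than 1,000 bp is dropped).  Each fragment is placed on the reference by
shared 16-mer seeding on both strands (seeds sampled every 4 bp; the most
supported diagonal wins, smallest diagonal on ties) and aligned to the
seeded candidate region — the diagonal ± 20 % of the fragment length — with
edlib's global alignment of the fragment into the region.  Identity is
matches / alignment columns from the alignment path, so gap columns count
in the denominator.  A fragment is retained when it aligns over at least
70 % of its length with at least 30 % identity; ANI in one direction is the
mean identity of retained fragments, and the reported ANI is the mean of
the two directions, which makes the value exactly symmetric.  Contigs are
joined with an N spacer of k characters so that no k-mer or alignment
crosses a contig boundary.  Two unrelated genomes typically share no
16-mer seed in either direction (the expected number of shared 16-mers
between random 20 kb sequences is ≈ 0.1), which raises
`NoAlignableFragments` rather than reporting a meaningless number.

The alignment engine is edlib's edit-distance-optimal path rather than a
hand-scored banded dynamic program.  For the substitution-dominated pairs
on which ANI is meaningful the minimum-edit-distance path is the same
alignment a match/mismatch/gap-scored global aligner finds, the identity
definition (matches over columns) is identical, and the C implementation
keeps a full pairwise matrix over a genome database inside interactive
budgets.  On planted substitution-only pairs the fragment ANI agrees with
a whole-genome global-alignment oracle and with the closed-form expected
identity to well under 0.5 percentage points (measured in the test suite
and by `scripts/acceptance.py`).

Under the neutral mutation model of the generator, two genomes derived
from one ancestor at substitution rates `p_i` and `p_j` have expected
per-site identity `(1 − p_i)(1 − p_j) + p_i p_j / 3` — the last term is
both lineages mutating and converging on the same base.

## Dereplication

Greedy centroid clustering at ANI ≥ 0.99 (the redundancy threshold of the
upstream workflow).  Genomes are ordered by a quality score
`coverage × (1 / n_contigs) × total_length`, descending, ties broken by
genome id; the best unassigned genome seeds a cluster and absorbs every
unassigned genome within the threshold; the seed is the representative.
The score is a deliberately simple proxy for assembly-quality-based
representative choice, and greedy centroid clustering is the simplest
deterministic rule with the required behaviour; tools such as dRep offer
several secondary-clustering backends, none of which is a field standard.

## Strain tracking, prevalence, and AxP

Detection is iterative winner-takes-all containment scoring over canonical
k-mers (k = 23, odd so the canonical form is unambiguous).  All distinct
canonical k-mers of a sample's reads form the pool; each database strain is
scored as |strain k-mers ∩ pool| / |strain k-mers|; the best strain at or
above `min_score = 0.1` is emitted (ties to the lexicographically smaller
id), its k-mers are removed from the pool, and the loop repeats up to
`max_iterations = 5` times.  Distinct k-mers, not multiplicities, are used,
which makes the score a coverage-like fraction robust to uneven depth.
k, min_score and max_iterations are exposed as flags; the defaults are
chosen in the spirit of reference-based strain typing tools, which do not
publish a single canonical setting.

The detection model presumes a **dereplicated** database: when two database
strains share more than ~90 % of their k-mers (ANI ≳ 0.995), removal of the
winner's k-mers can push a genuinely present near-duplicate below
min_score.  At the 0.99 dereplication threshold used upstream this regime
is excluded by construction.

Prevalence is binary per sample: the fraction of samples with at least one
detection of the strain.  The AxP index is

    AxP = mean_ANI × prevalence × 100

with both factors as fractions in [0, 1] so AxP ∈ [0, 100]; mean_ANI
averages a strain's ANI to all *other* database genomes (self excluded —
including self would only shift every score).  Ranking is descending with
deterministic id tie-breaks.

## Protein comparison and PPOS

Local alignments are Smith–Waterman with BLOSUM62 and affine gaps in the
BLAST convention (a gap of length L costs 11 + L), computed with
Biopython's `PairwiseAligner`; the test suite checks the scores against an
independent exhaustive Gotoh dynamic program.  Identities are identical
aligned residues; positives are aligned pairs with substitution score > 0,
with identities always counted (this covers X–X, which BLOSUM62 scores
negatively).  PPOS = 100 × positives / alignment length, with gap columns
in the denominator and never in the numerator — the BLAST "Positives"
column.  E-values use fixed gapped Karlin–Altschul constants (λ = 0.267,
K = 0.041, no length correction); absolute e-values only matter near the
cutoffs used (1e−5 for best hits, 1e−10 for pangenome edges), where this
approximation is comfortably adequate.

Proteome-average PPOS is the mean PPOS over A→B best-hit pairs (ties by
subject id); a `--bidirectional` option averages both directions, since
the direction convention of the upstream tool is unstated.  Best-hit search
prefilters subjects to those sharing at least one 3-letter word with the
query; a pair excluded by that filter cannot reach the e-value cutoff in
practice, and `local_align` itself is always exact.

## Pangenome

The hit graph connects two genes when one exact local alignment passes all
of: e-value ≤ 1e−10, identity ≥ 50 % over alignment columns (gaps in the
denominator, the BLAST pident convention), and aligned span covering ≥ 80 %
of *both* sequences.  The alignment is symmetric in its arguments, so one
alignment per unordered pair decides the edge and the graph is
orientation-free.  Within-strain pairs are compared too, so paralogs
cluster into one family.  Edge weight is −log10(e-value) capped at 200.

Families are Markov clustering (MCL) components: self-loops at each node's
maximum incident weight (1 for isolated genes), column-stochastic
normalisation, then alternating expansion (matrix squaring) and inflation
(entrywise power 1.5, renormalise), pruning entries below 1e−8, until the
largest entry change falls below 1e−6 or 100 iterations (non-convergence
returns the current partition with a warning).  Clusters are the connected
components of the limit matrix; family ids are assigned in order of each
family's smallest member, making the output deterministic.  Inflation 1.5
is common pangenome practice and is exposed as a flag.  MCL on a
thresholded BLAST graph is the classic gene-family construction used by
pangenome pipelines such as PGAP.
Unique genes of a focal strain are families with at least one member in
the focal column of the presence/absence matrix and zero members
everywhere else; a focal-internal duplicate family is reported once.

## Differential expression

Genes with CPM < 1 in more samples than allowed are removed; the
"in at least how many samples" parameter defaults to the smaller group
size, so a gene expressed in one full condition survives.  TMM factors
follow Robinson–Oshlack: reference = sample whose upper-quartile count
fraction is closest to the mean; per sample, gene-wise M (log2 ratio of
count fractions) and A (mean log2 abundance) on genes nonzero in both
samples; double trimming (30 % of M on each side, 5 % of A); factor =
2^(precision-weighted mean of surviving M) with inverse delta-method
binomial variances as weights; factors rescaled to geometric mean 1.  The
implementation reproduces edgeR's `calcNormFactors(method="TMM")` to four
decimals on shared inputs (cross-checked in the test suite via Rscript).

Testing: counts are rescaled to the geometric-mean effective library size
and rounded; per gene, the control-group sum S1 is tested against the
total T = S1 + S2 with an exact conditional two-sided test (all outcomes
no more likely than the observed one), using the NB convolution identity
(sum of n i.i.d. NB(μ, φ) = NB(nμ, φ/n)); dispersion below 1e−8 falls back
to the binomial (Poisson) conditional law.  Gene-wise dispersion is method
of moments within each group, floored at 0, then shrunk halfway toward the
matrix-wide mean — a lightweight stand-in for empirical-Bayes shrinkage
that stabilises small-sample estimates.  log2 fold change is the
difference of group means of log2 CPM computed with a prior count of 0.5
for stability near zero.  A gene is significant iff |fold change| ≥ 2 and
Benjamini–Hochberg FDR ≤ 0.05; the contract is asserted on every result
row.  The count rounding introduces at most a sub-count perturbation per
gene and is exact when library sizes are equal.

## Synthetic data generator

The generator emulates the statistical structure each stage assumes:

* **Genomes** — a uniform-random ancestor; per-strain i.i.d. substitutions
  to a uniformly chosen different base at the configured rate (rates above
  0.3 are rejected; the closed-form identity model degrades), optional
  single-base indels split evenly between insertion and deletion, even
  splitting into a configurable number of contigs.  A two-level variant
  (`simulate_genome_clusters`) derives cluster ancestors from the master
  ancestor at a between-cluster rate and members at a within-cluster rate,
  producing planted dereplication clusters (the flat generator cannot:
  with independent rates from one ancestor, all low-rate strains are
  mutually close).
* **Metagenomes** — reads drawn uniformly from a strain chosen per read by
  the mixture probabilities, substring positions uniform over eligible
  starts per contig, optional i.i.d. per-base substitution error, constant
  quality "I".
* **Proteomes** — random family ancestor sequences (length uniform in the
  configured range over 20 amino acids); core families in every strain,
  accessory families in random subsets of at least two strains (so the
  planted unique map and the observed single-strain families coincide),
  unique families in exactly one strain; members diverge from the ancestor
  at the configured per-residue rate.
* **Counts** — gene base means log-normal around `baseline_mean` (σ of the
  log configurable; 0 pins every mean), NB counts with variance
  μ + φμ², planted genes' treated-group means multiplied by 2^log2FC,
  optional per-sample library factors; φ = 0 gives Poisson.

Default study conditions: 2,000 genes, 5 samples per group, dispersion 0.1,
baseline mean 100 — the small-sample two-condition design the DE stage
targets.  All randomness derives from the master seed through fixed
per-generator spawn keys, so every generator is independently reproducible
and reruns are byte-identical.

What the generator does **not** emulate: realistic error profiles and
quality strings, GC bias, repeats, plasmids, horizontal transfer,
positionally correlated mutations, protein domain structure, or
gene-length/GC effects on counts.  Passing tests therefore demonstrate
algorithmic correctness on the stated generative model, not performance on
real sequencing data — in particular, real genomes' repeat content makes
fragment placement harder than the simulation suggests, and real RNA-seq
dispersions are gene-dependent in ways the single-φ model flattens.

## Problem sizes

The verification suite uses desk-scale problems chosen to keep the full
checks interactive while leaving each statistical check well-powered:
18–20 kb genomes for ANI pairs and tracking databases (10 strains), 12 kb
genomes for 3×3 dereplication sets, 10–15 kb five-strain cohorts for
end-to-end AxP runs, 4-strain pangenomes with ~35 proteins, and 2,000-gene
count matrices over 20 seeds for DE error control.  Headline counts from
any particular real-data application of this workflow depend on database
and cohort snapshots and are not reproducible from synthetic data; all
verification here is property-based against planted truth.

## Known limitations

* Fragment ANI is undefined (raises) when either direction retains no
  fragment; callers that need a number for unrelated pairs (dereplication)
  map the exception to 0.
* The e-value model ignores composition and length corrections; e-values
  far from the cutoffs are indicative only.
* The exact NB test conditions on rounded common-scale counts; with very
  unequal library sizes the rounding perturbs the conditional law slightly.
* Strain tracking assumes a dereplicated database and error-free-ish
  reads; heavy sequencing error shrinks containment scores toward the
  detection threshold.
* MCL is dense (O(n²) memory in the gene count) — appropriate for the
  tens-to-hundreds of genes per synthetic pangenome, not for
  hundred-thousand-gene graphs.
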