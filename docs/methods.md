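# Methods

## Overview

`introquant` quantifies introgression between congeneric species from
shotgun reads and compares its extent between two genera. The pipeline has
four statistical components — a generative model for synthetic data, a
competitive mapper, a coverage-ratio statistic with a contamination-aware
GLM, and a phylogenetic-network proportion test — described here with their
assumptions, parameters, and the design choices that were genuinely open.

## Synthetic data model

Each genus is simulated as a **star phylogeny**: every locus has one
ancestral sequence (i.i.d. bases at the requested GC content, default
0.38), and each species' copy substitutes every site independently with
probability *d*/2 to a uniformly chosen different base (Jukes–Cantor-like,
no indels). Expected pairwise divergence between two species is then
*d* − *d*²/3 (two independent branches, minus coincident hits), ≈ *d* for
the small values used. The star topology is deliberate: the analysis
contrasts genera, not within-genus topology, and a star makes the
per-genus divergence a single interpretable dial.

Reads are single-end, drawn from a uniformly random position of a uniformly
random locus, with i.i.d. per-base substitution errors (default 0.002).
Pairing is omitted because the coverage-ratio statistic depends only on
per-base depth, not inserts. Read-level **admixture** assigns each read to a
donor species with probability α (else the focal species); this is the
generative stand-in for introgressed ancestry. Block-level (haplotype)
admixture is not modelled — read-level mixing is exactly what a
coverage-ratio can measure, so tests on these data validate the estimator,
not the population genetics of real introgression.

**Index swapping** moves each read independently to a uniformly chosen
other sample with probability `swap_rate`, conserving total read count and
keeping origin tags for auditing.

### The 71-sample preset

The default study layout has a 5-species wing-louse genus (30 individuals)
and a 7-species body-louse genus (41 individuals), 71 samples total,
round-robin over species. Conditions, chosen once:

| parameter | wing | body | rationale |
|---|---|---|---|
| loci per species | 1039 | 1095 | reference panel sizes of the motivating study (tests use 100 for runtime) |
| locus length | ~350 ± 60 bp (floor 150) | same | exon-scale loci |
| interspecific divergence *d* | 0.05 | 0.10 | wing lice are the less divergent genus |
| admixture α per individual | U(0.05, 0.25), one donor | U(0, 0.08) | the dispersal hypothesis: more introgression in wing lice; magnitudes are generator choices sized to give clearly separated but overlapping score distributions |
| depth | 30× | 30× | middle of the 25–60× range typical for this kind of multiplexed data |
| read length | 150 bp | 150 bp | standard short-read length |
| error rate | 0.002 | 0.002 | post-trimming Illumina substitution scale |
| swap rate | 0.02 | — | within the 1–9% misassignment range reported for index swapping |

Reduced problem sizes used by the test suite and the acceptance script
(100 loci × 300 bp; toy panels of 10 loci) are runtime choices; every
statistical contract is size-invariant and the full-size preset runs
unchanged.

## Competitive mapping

All species' loci of a genus are indexed together (forward strand, k-mer
size 21). For each read, every k-mer (step 1) proposes the diagonals it
could start at; each distinct (read, diagonal) candidate whose window lies
inside one locus is scored by **ungapped match count** over the full read.
Per species the best candidate wins, ties going to the lowest
(locus, position); the best species wins overall. The **margin** — best
score minus the best score of any other species, 0 on cross-species ties,
and equal to the best score when no other species produced a seeded
candidate — is the mapping-quality proxy; hits with margin < 2 (default)
are discarded, playing the role of the conventional MQ > 3 uniqueness
filter. Ungapped scoring is exact here because the generator emits no
indels, which also keeps the exhaustive slide-and-score oracle in the test
suite exact. A `both_strands` option reverse-complements the read and keeps
the better orientation; the simulator emits forward-strand reads, so it is
off by default. The inner loop is a numba-compiled kernel; its outputs are
identical to the reference implementation of the same algorithm and are
checked against the exhaustive oracle in the tests. Coordinates are 0-based,
half-open.

k = 21 is a standard seed size: long enough that random collisions are
negligible at panel scale (4²¹ ≫ panel length), short enough that a
150 bp read from a 5–10% divergent wrong species still seeds occasionally,
letting the margin — not seed absence — do the discrimination.

## Coverage and the introgression score

Filtered hits increment per-base depth over their half-open interval. A
species' **mean coverage pools all its reference positions, zeros
included** (genome-wide mean). The alternative — average per-locus means,
then across loci — is available (`per_locus_mean`); the two agree exactly
for equal-length loci and the pooled form is the default because it matches
genome-wide mean-coverage semantics. The score is
Σ non-focal mean coverages / focal mean coverage; a sample whose focal
species has zero coverage is an error (reference/sample mismatch), and
zero non-focal coverage gives score 0. Under the generative model with one
donor at fraction α and divergence ample for unique mapping, the expected
score is α/(1−α); the test suite verifies slope ≈ 1 of score against
α/(1−α) over an α grid.

## Contamination simulation and GLM

To keep index-swapped reads from inflating the comparison, the analysis
subtracts putative contamination before refitting: per sample, a total mass
equal to `max_fraction` (default 0.09) × (sum of non-focal mean coverages)
is split across non-focal species by normalized uniform weights and
subtracted, flooring at zero (`allocate`, default). An alternative reading
— one u ~ U(0, 0.09) per sample scaling all non-focal coverages by 1−u
(`uniform_fraction`) — is provided because the verbal description of this
procedure admits both; `allocate` is the default as the cumulative-9%
interpretation. Only non-focal coverages are reduced: subtracting from the
focal species would *raise* the score, the opposite of removing
contaminant signal. Either mode can only decrease scores, and
`uniform_fraction` bounds the adjusted score in [score × 0.91, score].

Each of `n_iter` (default 100) iterations uses seed `seed + i`, refits the
GLM, and exports (F, df, p, R²); the **headline** GLM is fitted to each
sample's mean adjusted score. The GLM is Gaussian with identity link —
i.e. OLS, fitted via statsmodels after rank-revealing QR with column
pivoting drops aliased design columns. The headline formula is
**genus-only** (residual df = n − 2, i.e. 69 at n = 71); a
`genus_plus_species` formula is provided, but species is nested within
genus, so its indicators alias the genus column and are partially dropped
with a logged warning — which is why the genus-only model is headline.
Residual normality is exported as Q–Q data (Blom plotting positions against
ordered residuals), not as a test statistic. A residual sum of squares
below 1e−12 × TSS flags the fit "saturated" (R² = 1, p = 0).

## Network summaries and the proportion test

Extended-Newick networks are parsed by a small recursive-descent parser
(branch lengths accepted and ignored; errors report the offending
position). A reticulation is a **distinct** `#H` tag, however many times it
appears; a tip carrying a `#H` tag is a hybrid-node occurrence, not a leaf.
No installed library parses eNewick hybrid tags, so the parser is
in-package, with a generator of random networks with known counts serving
as its round-trip oracle.

The two genera are compared by treating reticulation counts as successes
out of *n* choose 2 leaf pairs (the number of species pairs that could have
hybridized). The test is the classical two-proportion χ² on the 2×2 table
with Yates correction (each |O−E| reduced by min(0.5, |O−E|) — capped so
near-null tables cannot go negative), df = 1. The confidence interval for
p₁−p₂ is the Wald interval widened by 0.5(1/n₁+1/n₂) under continuity,
clamped to [−1, 1]; one-sided tests use the one-sided normal quantile and
pin the unbounded end at ±1, and the one-sided p-value halves the
chi-square tail when the observed difference matches the alternative
(1 − half otherwise). These conventions jointly reproduce R's
`prop.test`, which the test suite uses as a frozen oracle. With the study's
counts — 7 reticulations among 15 wing-genus pairs (6 network leaves)
versus 4 among 28 body-genus pairs (8 leaves) — the test gives
χ² = 3.8132, one-sided p = 0.025 with CI (0.03, 1), two-sided p = 0.051
with CI (−0.01, 0.66). The denominators are explicit user inputs
everywhere: leaf counts include outgroup/ghost leaves present in the
networks, so they are a property of the networks supplied, not of the
ingroup species lists. Candidate networks with different reticulation
counts are ranked by AIC = 2k − 2·log pseudo-likelihood, ties going to
fewer reticulations.

## Numerical and formatting choices

- All randomness flows from explicit integer seeds (numpy `default_rng`);
  study-level runs derive per-sample seeds from the root seed, and reruns
  are byte-identical.
- TSV outputs carry `#`-prefixed metadata lines including a 12-hex
  configuration hash (output directory and log level excluded from the
  hash, since they do not affect results). FASTA/FASTQ have no portable
  comment syntax, so sequence files are instead recorded in the run's
  `provenance.json`.
- Exit codes: 0 success, 2 validation error, 3 runtime error.

## Limitations

The generator omits paired-end structure, indels, quality-score ramps,
coalescent gene-tree heterogeneity and block-structured admixture; passing
tests therefore demonstrate that the estimator and inference chain behave
correctly under the stated generative model, not that real louse data meet
that model. The mapper is ungapped and forward-strand by default, and makes
no attempt to reproduce any particular aligner's mapping-quality values.
Network *inference* (maximum pseudo-likelihood search) is out of scope;
networks arrive as eNewick inputs. The published study-specific GLM values
(F = 21.07, R² = 0.58) depend on the real sequencing data and are not
reproduction targets; the synthetic pipeline reproduces the *direction* and
significance of the genus contrast, and the df/iteration structure exactly.
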