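# Methods

This note documents the models and procedures `protostrain` implements,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data tests do and do not show
about real data.

## ANI estimation

Pairwise average nucleotide identity is estimated from bottom-s MinHash
sketches of canonical k-mers (lexicographic minimum of each k-mer and its
reverse complement, 2-bit packed into unsigned 64-bit integers; windows
containing non-ACGT characters are dropped rather than expanded, to avoid
inflating marker sets). Hashing is a splitmix64 finaliser keyed by a user
seed, so sketches are reproducible across machines without any external
hashing dependency.

The Jaccard similarity J of two genomes' k-mer sets is estimated from the
merged bottom-s sketch (the intersection counted within the s smallest
hashes of the union — the standard unbiased estimator), and converted to
identity by the Mash point estimate

    ANI% = 100 · (1 + ln(2J / (1 + J)) / k).

Defaults: k = 23 (matching the k used for metagenome profiling, so one
k-mer substrate serves both stages), s = 5000, clamped to [0, 100] with
J = 0 mapping to 0. This sketch estimator stands in for
fragment-mapping ANI tools; it is a declared approximation, valid for the
94–100% range the pipeline uses and unreliable below ~80–85% identity.
The test suite calibrates it against the exact full-set Jaccard estimate
on 200 kb genome pairs at planted ANI 95 / 98 / 99.8: at s = 5000 the
sketch error is a few hundredths of an ANI point at high identity and
~0.1 at ANI 95, comfortably inside the ±0.5-point acceptance band.

## De-replication

Genomes first pass a species gate (ANI to the designated type/reference
genome ≥ 94%; values strictly below are rejected) and a quality gate
(completeness ≥ 90, contamination ≤ 5 by default — community-standard
high-quality thresholds, configurable; the quality values themselves are
inputs, not estimated here). Lineages are then formed at strictly
greater than 99.8% ANI. Default linkage is single — connected components
of the >99.8% graph — which is order-independent and matches greedy
secondary clustering closely; complete linkage is available through
scipy's hierarchical clustering (with a `nextafter` nudge so the strict
inequality is honoured at the merge threshold).

Each clade's representative maximises completeness − 5·contamination,
ties broken by genome length then lexicographic id — a fully
deterministic dRep-style score. The mean intra-clade ANI (the AxP "ANI
term") is the arithmetic mean over unordered member pairs; a singleton
clade takes 100.0 by the self-identity convention. Because published
lineage tables sometimes carry an ANI term computed against a different
referent (e.g. the species reference rather than clade-internal pairs),
the ANI term fed to AxP is configurable: `mean_intra_clade` (default),
`ani_to_reference`, or user-supplied values taken as given.

## Prevalence and the AxP index

A lineage's marker set is its representative's canonical 23-mers minus
the union of all other representatives' k-mers; marker sets of distinct
lineages are disjoint by construction, so a sample containing only a
sibling lineage scores zero breadth even at >99% whole-genome identity.
Detection in a sample is marker breadth ≥ 0.5 (the threshold is exposed;
breadth-style criteria are the norm for presence calls, and at this
marker resolution planted-truth breadth is essentially bimodal at 0 and
1, so the result is insensitive to the exact cut-off). Cohort prevalence
is the exact fraction count / n over **all** cohort samples — the only
denominator under which published AxP values back-solve to integer
detection counts — stored unrounded because the percentage printed in
reports is too coarse to regenerate AxP.

    AxP = ANI term × prevalence × 100,       AxP ∈ [0, 10000]

ranked descending per cohort; ties broken by higher ANI term then
lexicographic lineage id (ties are not expected in practice; the rule
just makes the ranking total and deterministic).

## PPOS matching

Candidate proteomes are compared to the prototype proteome by reciprocal
best hits under affine-gap alignment with BLOSUM62, gap open 11 and
extend 1 (BLASTP-default-like scoring; a gap of length L costs
11 + L·1). The default alignment mode is global with free end gaps — the
usual convention for full-length ortholog comparison; local alignment is
available. Alignment statistics are computed over the aligned region
(terminal free-end gap columns excluded): PPOS = 100 × (columns whose
substitution score is positive) / (aligned columns), which is ≥ percent
identity by construction for standard residues.

The candidate's average PPOS aggregates pair PPOS values as an
unweighted mean by default; a length-weighted mean is available. This
aggregation is the major interpretive decision in the module — upstream
tooling for this step is unpublished — so it is exposed as configuration
rather than hard-coded. The selection score is ANI × avg PPOS, ranked
descending.

An exact-word seeding heuristic (≥ 2 shared 4-mers by default) limits
alignment to plausible homolog pairs; unrelated random proteins share
multiple exact words with negligible probability, while pairs at the
identity levels this pipeline pairs share dozens. Sequences too short to
carry enough words bypass the filter and are always aligned.

## Pangenome

All proteins of all genomes are compared all-vs-all (same seeding
heuristic, local alignments). An edge is kept iff E-value < 1e-5 AND
identity ≥ 50% AND the alignment covers ≥ 80% of **both** sequences.
E-values use the Karlin–Altschul relation E = K·m·n'·exp(−λS) with the
gapped BLOSUM62-11-1 constants λ = 0.267, K = 0.041 and search space =
query length × total database residues — an analytic stand-in for a
BLAST search's reported E-value, adequate because family-level scores
sit many orders of magnitude below the cut-off while chance hits sit
above it.

Families are connected components of the kept-edge graph by default;
Markov clustering (inflation 1.5) is available behind a flag for
tighter granularity. Classification: core iff a family spans all N
genomes, unique iff exactly one (its members are that genome's TUGs),
dispensable otherwise; with N = 1 every family is classified unique
(truly-unique-gene semantics dominate for singleton inputs). The
identities pangenome = core + dispensable + unique and Σ family sizes =
total gene count hold exactly.

## Co-occurrence statistics

* **Correlation screen** — Spearman rho of every species against the
  focal species (average ranks for ties; p from the t-approximation,
  matching common implementations at cohort-scale n), BH step-up
  adjusted across all tested species; the positive-correlation filter
  keeps rho > 0 at FDR < 0.05.
* **Ordination screen** — Bray–Curtis dissimilarity
  BC = 1 − 2·Σmin/(Σx+Σy); PCoA by Gower double-centering and
  eigendecomposition, axes ordered by descending eigenvalue, negative
  eigenvalues reported (BC is non-Euclidean) rather than silently
  dropped. envfit-style fitting regresses each species vector onto the
  first two ordination axes (configurable); R² is the squared multiple
  correlation, tested by 999 seeded permutations with p floored at
  1/(n_perm+1). The filter keeps R² > 0.2 at FDR < 0.01.
* **Partner selection** — intersection of both filters, sorted by rho.
* PERMANOVA (pseudo-F, 999 permutations, via scikit-bio) is available
  for population-difference questions but is not part of partner
  selection.

Whether the envfit FDR should be computed over all species or only the
correlation-screen survivors is a genuinely open choice; the screen
accepts an explicit species subset so either convention can be run.

## Synthetic data

Generators are pure functions of (parameters, seed) and serialize their
planted truth next to the data:

* **Genomes** — uniform random ancestor; each lineage derived by i.i.d.
  substitutions at rate 1 − ANI/100 (target ANI must exceed 80, the
  sketch-ANI validity floor). Substitution-only evolution keeps the
  ANI/k-mer arithmetic analytically checkable; real genomes also differ
  by indels, rearrangements and horizontal transfer, which this model
  does not emulate — passing tests certify the estimator and the
  detection logic, not robustness to structural variation.
* **Cohorts** — each sample carries the k-mers of a fixed set of random
  background genomes plus, with independent Bernoulli(prevalence)
  draws, full lineage genomes. Real metagenomes contain partial genomes
  at varying coverage and sequencing error; the breadth threshold exists
  precisely to absorb such effects, but the synthetic tests exercise the
  clean limit.
* **Proteomes** — planted core families (all genomes), dispensable
  families (random proper subsets of ≥ 2 genomes), and per-genome TUGs
  with no homolog elsewhere; within-family divergence ≤ 0.2 so the
  clustering cut-offs are guaranteed to hold.
* **Abundances** — log-normal species abundances; species tied to the
  focal species through a Gaussian copula with latent Pearson
  r = 2·sin(π·ρ_S/6), which plants an exact target Spearman correlation;
  rows renormalized to relative abundance (the renormalization perturbs
  rank correlations slightly, shrinking with the species count). Joint
  feasibility (Σr² ≤ 1) is checked and infeasible requests rejected.

## Problem sizes used in the automated checks

Worked examples run on the bundled published tables (37 lineages;
adult cohort n = 4,019) in milliseconds. The calibration and recovery
suites use 200 kb genome pairs (51 pairs across three ANI levels); 40
seeded end-to-end cohort runs with 5 lineages of 30 kb, 300 samples and
prevalences 0.35/0.25/0.15/0.08/0.03; pangenomes of 5 genomes × (500
core + dispensable + 30 TUGs) families; and 200-replicate null suites
for the statistics. These sizes give the binomial and permutation
statistics enough resolution for the stated acceptance margins while
keeping the full suite around five minutes on one CPU.

## Numerical and degenerate-input choices

* k must be odd (no k-mer equals its own reverse complement) and ≤ 31
  (2-bit packing in 64 bits); k shorter than the sequence yields an
  empty k-mer set with a warning, not an error.
* Sketches smaller than s (genome has fewer distinct k-mers) are kept
  whole and flagged rather than rejected.
* Two k-mer-identical lineage representatives yield empty marker sets
  for both, emitted with a warning; their detection breadth is reported
  as NaN and they are never called present.
* A constant focal-abundance vector is an error (rho undefined); a
  constant species vector in envfit returns R² = 0, p = 1.
* Set operations on k-mer arrays use quicksort-based deduplication
  rather than stable sorts — identical results, several-fold faster on
  genome-scale uint64 arrays.

## Known limitations

* Sketch ANI is a point estimate without confidence intervals and is
  not meaningful below ~80–85% identity.
* Marker-based detection reports presence, not abundance; SNV-level
  profiling is out of scope.
* The Karlin–Altschul constants are fixed for BLOSUM62-11-1; other
  scoring schemes would need their own (λ, K) or the bit-score proxy.
* The co-occurrence screen is correlational: partner species are
  candidates for interaction, not demonstrated mutualists.
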