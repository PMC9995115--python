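# Methods

`tcrshare` implements the quantitative core of a spatial/temporal TCRβ
repertoire study of paired inflamed compartments: clone sharing between the
synovial fluid of two affected joints and peripheral blood, persistence of
dominant clones across clinic visits, discrimination of convergent
recombination from antigen-driven convergent selection via generation
probabilities, rarefaction/extrapolation diversity, and CDR3 k-mer
similarity networks benchmarked against random repertoires from a generative
V(D)J model. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not show.

## Clonotype conventions

A clonotype at ingestion is keyed by `(junction_aa, v_call, j_call)` with a
template count; frequencies are always recomputed from counts, never trusted
from files. Every cross-sample comparison (overlap, Venn, networks, p_gen)
first collapses to the amino-acid junction alone, because clone sharing
between independently sequenced samples is defined on the amino-acid
sequence; V-call nomenclature drift across samples would otherwise split
identical clones. Junctions containing `*` or `X` are retained at ingestion,
flagged non-productive, and excluded from p_gen and network stages.
Singleton clonotypes are not filtered by default (a `min_count` option
exists); top-N rankings break count ties lexicographically so all statistics
are independent of input row order.

## The recombination model and exact p_gen

The generative model is V–insertion–J: a junction is a V 3'-suffix trimmed
by `del_V ~ v_deletion_pmf`, followed by `L ~ insertion_length_pmf` i.i.d.
nucleotides, followed by a J 5'-prefix trimmed by `del_J`. The D segment and
the two physiological insertion zones are deliberately collapsed into one
insertion segment. What this preserves is exactly the property the analyses
rely on: junctions reachable by many scenarios — short, low-insertion ones —
have high generation probability, so convergent recombination produces a
positive frequency–p_gen coupling under neutral expansion. What it gives up
is D-segment alignment detail and dinucleotide (Markov) insertion bias; both
are documented limitations, acceptable because p_gen is used as a covariate
and a null generator, not as an absolute rate to be matched against an
external tool.

`pgen_nt` is the exact sum of `P(V)P(del_V)P(L)∏P(nt)P(del_J)P(J)` over all
scenarios whose concatenation equals the query, organised as a loop over the
(V-remnant, J-remnant) split points with the insertion mass computed in
closed form. `pgen_aa` sums `pgen_nt` over all coding nucleotide sequences
without enumerating codon combinations: complete codons inside the V (or J)
remnant must literally encode the corresponding residue; codons fully inside
the insertion contribute a precomputed per-residue codon mass; at most two
boundary-straddling codons are summed over the ≤6 codons of their residue
with fixed positions constrained and free positions weighted by the
insertion nucleotide law. A reference pure-Python implementation and a
numba kernel compute the identical sum (~0.25 ms vs ~0.01 ms per junction);
both are tested to 1e-12 against an exhaustive scenario-enumeration oracle
on five toy models (the oracle refuses models above 10⁶ scenarios). p_gen is
not conditioned on productivity, matching the common convention; amino-acid
queries are by construction productive-level quantities.

The packaged toy model (`models/toy_trb.yaml`) has 8 V suffixes (15 nt,
codon-aligned, starting at the conserved Cys) and 6 J prefixes (18 nt,
ending on Phe), deletions 0–4 nt, insertions 0–10 nt with a GC-biased
nucleotide law, and mildly skewed segment usage. Segment amino-acid prefixes
were chosen distinct so that V/J identity alone yields at most 7 shared
3-mers — one below the similarity-network edge threshold — keeping the
random-network null subcritical at study sizes (see below). Junction frame
starts at position 1 of the V suffix; translation uses the standard genetic
code (table taken from Biopython).

## Synthetic cohorts and their ground truth

Each sample draws `repertoire_size` **unique productive** junctions
independently from the model. There is no shared latent pool: cross-sample
background sharing arises only from convergent recombination (the same
high-p_gen junction drawn in two samples), and planted sharing is the only
other source. This makes the NEUTRAL cohort law identical to the law of the
size-matched random repertoires used in the network benchmark, which is what
keeps that comparison's null calibration honest by construction.

Clone sizes follow a Zipf law over ranks, `w_r ∝ r^(−α)` with α = 1.5
(default), realised as a multinomial draw of `reads_per_sample` (default
50 × repertoire_size) reads over ranks with a floor of one read per
clonotype. α and the read depth are free parameters of the generator — the
clone-size law of the motivating data is not quantified — chosen to produce
hyper-expanded tails (top clone at tens of percent of reads) like those seen
in sorted synovial Treg repertoires.

Selection modes:

* **NEUTRAL** — ranks are assigned to clones by noisy generability score
  `log10 p_gen + N(0, σ)`, σ = 2.0. Expansion is therefore coupled to p_gen
  (convergent recombination); σ was fixed once so that the non-shared
  frequency–p_gen Spearman ρ is ≈ 0.3–0.5 at default sizes, the magnitude
  typical of reported per-sample correlations. Nothing is planted.
* **ANTIGEN** — the NEUTRAL background plus planted structure: (i) shared
  clones drawn from the model and copied into the configured compartments
  and visits with ranks drawn uniformly in a hyper-expanded band
  (default top-100) **independently of their p_gen** — convergent selection;
  Tregs receive `treg_multiplier` (default 2×) as many as non-Tregs; and
  (ii) similarity-cluster families: a 13–15 aa seed junction plus members
  differing by one substitution, planted as a star (the seed is a member) so
  that every member shares ≥8 3-mers with the seed — two members can be two
  substitutions apart and fall below the threshold, so the star is what
  guarantees one connected component. The member→compartment cycle is
  (LEFT, RIGHT, BOTH): some family members are themselves cross-joint
  shared clones, so planted clusters mix three origin labels and their
  purity (≈3/8) sits strictly below the minimum purity (0.5) of a mixed
  two-node cluster in a random pair.

The generator emits standard clonotype tables, a sample sheet, and a ground
truth file (planted keys, family memberships); identical seeds give
byte-identical tables (all randomness flows from `SeedSequence` tuples keyed
by patient/subset/compartment/visit).

What the synthetic cohorts do **not** emulate: sequencing error and PCR
amplification bias, thymic selection, V/J-conditioned junction composition
beyond the toy segments, and any real clone-size law. Passing tests
demonstrate that the pipeline's statistics recover the planted structure
under the stated generative assumptions — not that real repertoires satisfy
those assumptions.

## Overlap and persistence statistics

Clonal proportions bin total read mass by clone count (default bins 1, 2–9,
10–99, ≥100 — an artifact convention). Top-N sequential intersection
reports `100·|top_n(A) ∩ top_n(B)|/n` over a log-spaced grid 1…1000; Jaccard
matrices are set-based over unique junctions (presence, not frequency);
sharing classes count the samples containing each junction; Venn regions are
computed over top-100 sets and sum to the union size. All are deterministic
and row-order invariant.

## Convergence analysis

For each within-patient sample pair, clones are split into SHARED /
NON_SHARED by presence in both junction sets. Shared clones take the maximum
of their two within-sample frequencies (configurable: max or mean; the
choice only reindexes ranks and barely moves ρ). Spearman ρ with average
ranks is computed against `pgen_aa`; clones with p_gen = 0 under the toy
model (e.g. planted family mutants that leave the model's image) are
excluded and counted. The reported 95% CI uses the Fisher z transform with
SE √(1.06/(n−3)). A least-squares line on log10–log10 axes is attached for
plotting only; ρ itself is scale-free (verified by a LOG10 vs LINEAR
invariance test). Groups with n < 3 or constant values are flagged
UNDEFINED, never dropped. Per-pair p-values are reported raw with a
Benjamini–Hochberg column.

## Diversity

Richness interpolation uses the exact hypergeometric expectation
`Ŝ(m) = S_obs − Σ_i C(n−n_i, m)/C(n, m)` via log-gamma; extrapolation uses
the Chao1 estimate of undetected richness
`f̂0 = ((n−1)/n)·f1²/(2f2)` (the `f1(f1−1)/2` form when f2 = 0). Shannon
(Hill q=1) interpolation is `exp` of the mean entropy of `b_reps` (default
200) seeded hypergeometric subsamples; this deviates from the closed-form
estimator used by the standard R implementation on purpose — the Monte-Carlo
form is directly checkable against exhaustive subset enumeration on toy
communities, and for group comparison only the ordering at a common size
matters. At m = n the plug-in value is returned exactly; beyond n a
coverage-adjusted (Chao–Shen) asymptotic entropy plateau is reported and
flagged EXT. Group contrasts are two-sided Mann-Whitney tests on per-sample
estimates at the largest common sample size (the comparison size is an
artifact convention; the motivating analysis does not state one).

## Similarity networks

Nodes are unique junctions (left/right origin labels merged; a junction in
both samples is one SHARED node). Edge rule: ≥ `tau` = 8 shared **distinct**
3-mers, independent of junction length — k-mer presence is counted once,
never multiplicity. Edges are found via a sparse node×k-mer incidence
product; clusters are connected components with deterministic ids
(decreasing size, then lexicographically smallest member). No trimming of
the conserved anchor residues is applied by default (`trim_anchors` exists);
anchor-induced baseline similarity is part of the rule.

Cluster purity is the share of nodes carrying the most common origin label
(LEFT/RIGHT/SHARED). The alternative literal reading — share of the most
abundant *sequence* — is degenerate on unique-sequence nodes; it is
implemented count-weighted behind `purity_mode="sequence"`, but the
label-based reading is the default because it is the one under which random
repertoires are "less mixed" (high purity) than patient networks. The
benchmark generates `n_random` = 100 independent random left/right pairs
matched in unique-sequence count (sampled productive-only, deduplicated),
collects top-5 cluster purities, and reports a two-sided Mann-Whitney test
of patient vs random purity.

A density caveat: chance k-mer percolation grows with repertoire size. With
the packaged toy model, random 300-junction pairs give small, side-pure
chance clusters (the regime the purity contrast assumes), while 2,000-
junction pairs already percolate into 15–30-node mixed chance clusters.
Real CDR3 space is astronomically larger, so real repertoires sit in the
subcritical regime at much larger n. The packaged default cohort therefore
plants 40-member families (larger than the biggest chance cluster at
default sizes), and the operating-characteristic studies run at 300
clonotypes/sample, six 8-member families — sizes chosen to be the
paper-like regime for the toy model.

## Statistics

Spearman ρ uses average ranks; p from the t approximation with n−2 df. An
exact permutation p (n ≤ 8) is provided using the **mid-p** convention
(half-weight on permutations exactly as extreme): the permutation null at
these n is very discrete, and mid-p is the comparable quantity for a
continuous approximation — with it the t approximation agrees within 0.05
at n = 5, which the conservative ≥-counting convention cannot guarantee.
Mann-Whitney U is two-sided, exact when min(n) ≤ 8 and tie-free (matching
plain enumeration, e.g. p = 1/3 for {1,2} vs {3,4}), tie-corrected normal
otherwise; all-tied inputs return p = 1 flagged ALL_TIED. Both are thin
wrappers over scipy.stats pinned to these conventions; the enumeration
oracles in the tests are independent implementations.

## Pipeline and reproducibility

Stage seeds derive from SHA-256 of `(global_seed, stage_name)`, so the
random-repertoire benchmark changes with the global seed while patient
networks (deterministic given the cohort) do not. Every output table carries
a provenance header (`version, stage, seed, config hash` — the hash covers
the scientific configuration, not the output path). Full default runs are
byte-identical across reruns; the default end-to-end run (16 samples ×
2,000 clonotypes, ~33k distinct p_gen evaluations, 2×101 networks of ~3,800
nodes) completes in ~70–90 s. The `analysis/` scripts are thin narrative
drivers over the same `tcrshare.pipeline` stage functions the tests import.

## Known limitations

* The V–ins–J model cannot reproduce external-tool p_gen values numerically;
  correlations against such values are out of scope by design.
* The toy model's junction space is small enough that chance network
  percolation appears at a few thousand nodes (see caveat above).
* Shannon interpolation is Monte-Carlo: group comparisons inherit its
  (seeded, reported) sampling error.
* NEUTRAL-mode frequency–p_gen coupling is a single-knob (σ) phenomenological
  stand-in for repeated generation-and-sampling; it reproduces the rank
  correlation, not the mechanistic count distribution.
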