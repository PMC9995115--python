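# tcrshare

Spatial and temporal analysis of TCRβ repertoires from paired inflamed
compartments: clone sharing between the synovial fluid (SF) of two affected
joints and peripheral blood, persistence of dominant clones across clinic
visits, generation-probability-based discrimination of convergent
recombination from antigen-driven convergent selection, rarefaction /
extrapolation diversity, and CDR3 k-mer similarity networks benchmarked
against random repertoires from a generative V(D)J model.

It is written for immunologists analysing clonotype tables from sorted
T-cell subsets (e.g. Treg vs conventional CD4⁺ cells in juvenile idiopathic
arthritis) who want to ask: *are the dominant clones in two inflamed sites
the same clones, do they persist through relapse and remission, and is their
expansion explained by recombination statistics or by antigen?*

## The quantities at the core

* **Sharing.** For samples A, B with unique amino-acid junction sets, the
  Jaccard index J(A,B) = |A∩B| / |A∪B|; sequential top-N intersection
  100·|topₙ(A) ∩ topₙ(B)|/n; top-100 Venn region counts; per-clone sharing
  classes (present in 1, 2, or 3 of PB / SF-left / SF-right).
* **Generation probability.** For a junction σ, p_gen(σ) = Σ over all
  recombination scenarios (V choice, V trimming, insertions, J trimming, J
  choice) whose product equals σ of P(V)·P(del_V)·P(ins)·P(del_J)·P(J),
  computed exactly at nucleotide and amino-acid level by dynamic programming
  over a V–insertion–J model. Convergent recombination predicts Spearman
  ρ(frequency, p_gen) > 0; antigen-driven selection predicts ρ ≈ 0 for the
  shared, hyper-expanded clones.
* **Diversity.** Hill numbers q=0 (richness) and q=1 (exp Shannon entropy)
  by sample-size-based rarefaction (exact hypergeometric expectation) and
  extrapolation (Chao1), compared between groups at a common size by
  Mann-Whitney U.
* **Similarity networks.** Nodes are unique junctions labeled by joint of
  origin; an edge joins two junctions sharing ≥ 8 distinct amino-acid 3-mers;
  clusters are connected components; cluster purity is the share of the most
  common origin label. Patient networks are compared against 100
  size-matched random repertoires sampled from the same V(D)J model.

A fully specified synthetic-cohort generator (`tcrshare.cohort`) provides
ground truth for all of this: Zipf clone sizes, p_gen-coupled neutral
expansion, planted cross-joint/cross-visit hyper-expanded clones, and
planted sequence-similar clone families. See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (2 patients × 2 knees × Treg/non-Treg × 2 visits, 2,000
clonotypes per sample) and write their tables under `results/analysis/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_convergent_selection.py
python analysis/06_similarity_networks.py
```

The convergence driver prints, per patient/subset and sample pair, the
Spearman correlation between clone frequency and generation probability by
sharing group:

```
patient   subset      group    n       rho             p
     P1     TREG     SHARED  282  0.039383  5.101030e-01
     P1     TREG NON_SHARED 3222  0.319054  3.777545e-77
     P2     TREG     SHARED  289 -0.015382  7.945710e-01
     P2     TREG NON_SHARED 3184  0.364471 1.271766e-100
```

Clones found in only one knee show a strong positive frequency–p_gen
correlation (ρ ≈ 0.32–0.36): their abundance tracks how easily the
recombination machinery generates them. Clones shared between both knees
show none (ρ ≈ 0, p > 0.5): their expansion is not explained by
generability — the signature of antigen-driven selection.

The network driver prints the top-5 similarity clusters and the
random-repertoire benchmark:

```
patient  cluster_id  n_sequences  n_connections   purity top_label
     P1           0          113            412 0.371681      LEFT
     P1           1           63            255 0.444444     RIGHT
...
patient  u_statistic  p_value  n_patient  n_random
     P1         29.0 0.000168          5       500
     P2         10.0 0.000132          5       500

random cluster purity median: 0.512
```

Patient clusters are large (40–113 sequences) and mix left-knee, right-knee
and shared junctions (purity ≈ 0.35–0.44), while clusters in size-matched
random repertoires are small and side-pure (median purity 0.51): TCRs from
the two inflamed knees are more sequence-similar to each other than chance
recombination allows (Mann-Whitney p ≈ 1e-4), recovering the planted
antigen-driven clone families.

The same stages are available as a CLI (`tcrshare simulate|spatial|temporal|
network|diversity|all`, with `--config run.yaml --seed N --out DIR`), and as
library functions in `tcrshare.pipeline` for use on real sample sheets
(tab-separated manifest + AIRR-style clonotype tables; see
`tcrshare.io.load_cohort`).

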