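"""Validation studies: oracle agreement and Monte-Carlo operating characteristics.

Each function recomputes a quantitative property of the package from scratch
under fixed, documented study conditions (cohort sizes, replicate counts) and
returns plain numbers. They back both the acceptance test suite and
``scripts/acceptance.py``.

Study conditions: the planted-structure and convergence studies use
single-patient, Treg-only, two-joint cohorts of 300 clonotypes per sample
(the order of unique Treg junctions in a sorted synovial-fluid sample) with
30×2 planted cross-joint clones (so that antigen-driven sharing dominates the
incidental convergent-recombination sharing, per the generator's contract),
six 8-member planted families and 100 size-matched random repertoire pairs
per comparison.
"""

from __future__ import annotations

import itertools
import math
import os
import tempfile
import time
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import (
    CohortConfig,
    PlantedClusterSpec,
    PlantedSharedSpec,
    generate_cohort,
)
from .convergence import NON_SHARED, SHARED, correlate_freq_pgen, shared_nonshared_table
from .diversity import AbundanceVector, rarefied_richness, rarefy_shannon
from .network import LABEL_LEFT, LABEL_RIGHT, NetworkConfig, build_network, cluster_statistics, compare_to_random
from .stats import mann_whitney_u, spearman_correlation
from .vdj import (
    RecombinationModel,
    Segment,
    default_model,
    enumerate_pgen_aa_oracle,
    enumerate_pgen_oracle,
    pgen_aa,
    pgen_nt,
    sample_junctions,
)


def _sub_seed(base_seed: int, *key) -> int:
    ss = np.random.SeedSequence((int(base_seed), *[int(k) for k in key]))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Oracle agreement
# ---------------------------------------------------------------------------

def reference_toy_models() -> list[RecombinationModel]:
    """Five enumerable models spanning degenerate to multi-segment, biased cases."""
    u4 = np.full(4, 0.25)
    return [
        RecombinationModel([Segment("V1", "TGT", 1.0)], [Segment("J1", "TTT", 1.0)],
                           [1.0], [1.0], [1.0], u4, name="M1"),
        RecombinationModel([Segment("V1", "TGT", 1.0)], [Segment("J1", "TTT", 1.0)],
                           [1.0], [1.0], [0.5, 0.5], u4, name="M2"),
        RecombinationModel([Segment("V1", "TGT", 1.0)], [Segment("J1", "TTT", 1.0)],
                           [0.5, 0.5], [1.0], [0.5, 0.5], u4, name="M3"),
        RecombinationModel([Segment("V1", "TGTGCA", 0.6), Segment("V2", "TGCAGT", 0.4)],
                           [Segment("J1", "GAATTT", 0.7), Segment("J2", "TACTTC", 0.3)],
                           [0.5, 0.3, 0.2], [0.6, 0.4], [0.4, 0.3, 0.3], u4, name="M4"),
        RecombinationModel([Segment("V1", "TGTGCAAGC", 0.5), Segment("V2", "TGCAGTGTA", 0.3),
                            Segment("V3", "TGTGCC", 0.2)],
                           [Segment("J1", "GCTTTCTTT", 0.5), Segment("J2", "CAGTACTTT", 0.5)],
                           [0.4, 0.3, 0.2, 0.1], [0.5, 0.5], [0.3, 0.3, 0.2, 0.2],
                           np.array([0.1, 0.4, 0.4, 0.1]), name="M5"),
    ]


def pgen_oracle_benchmark(models: Sequence[RecombinationModel] | None = None) -> dict:
    """Max |p_gen − exhaustive oracle| over every generable sequence of every model."""
    models = list(models) if models is not None else reference_toy_models()
    max_nt_err = 0.0
    max_aa_err = 0.0
    max_total_dev = 0.0
    n_nt = 0
    for model in models:
        oracle = enumerate_pgen_oracle(model)
        max_total_dev = max(max_total_dev, abs(sum(oracle.values()) - 1.0))
        for nt, p in oracle.items():
            max_nt_err = max(max_nt_err, abs(pgen_nt(model, nt).pgen - p))
            n_nt += 1
        for aa, p in enumerate_pgen_aa_oracle(model).items():
            max_aa_err = max(max_aa_err, abs(pgen_aa(model, aa).pgen - p))
    return {
        "n_models": len(models),
        "n_sequences": n_nt,
        "max_nt_abs_error": max_nt_err,
        "max_aa_abs_error": max_aa_err,
        "max_total_probability_deviation": max_total_dev,
    }


def sampling_benchmark(model: RecombinationModel | None = None, n: int = 100_000, seed: int = 11) -> dict:
    """Empirical junction frequencies vs oracle probabilities, in binomial SE units."""
    if model is None:
        model = reference_toy_models()[1]  # M2
    oracle = enumerate_pgen_oracle(model)
    counts: dict[str, int] = {}
    for nt, _aa in sample_junctions(model, n, seed=seed):
        counts[nt] = counts.get(nt, 0) + 1
    worst = 0.0
    for nt, p in oracle.items():
        se = math.sqrt(p * (1 - p) / n)
        worst = max(worst, abs(counts.get(nt, 0) / n - p) / se)
    return {"n": n, "support_size": len(oracle), "max_se_units": worst}


def kmer_benchmark(n_pairs: int = 10_000, seed: int = 23, k: int = 3, tau: int = 8) -> dict:
    """shared_kmer_count vs brute-force intersection; pigeonhole edge bound."""
    from .network import shared_kmer_count

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    mismatches = 0
    for _ in range(n_pairs):
        la, lb = rng.integers(3, 20, size=2)
        a = "".join(rng.choice(alphabet, size=la))
        b = "".join(rng.choice(alphabet, size=lb))
        brute = len({a[i: i + k] for i in range(len(a) - k + 1)} & {b[i: i + k] for i in range(len(b) - k + 1)})
        if shared_kmer_count(a, b, k) != brute:
            mismatches += 1
    # adversarial inputs for the pigeonhole bound: short, repetitive, near-identical
    adversarial = ["CASSLSGTF", "CASSLSGT", "AAAAAAAAA", "A" * 30, "CASSLSGTA", "CASSLSGTC"]
    violations = 0
    pairs = [(x, "LEFT") for x in adversarial]
    net = build_network(pairs, NetworkConfig(k=k, tau=tau))
    for u, v in net.edges:
        if min(len(net.nodes[u]), len(net.nodes[v])) < tau + k - 1:
            violations += 1
    return {"n_pairs": n_pairs, "mismatches": mismatches, "pigeonhole_violations": violations}


# ---------------------------------------------------------------------------
# Planted-structure and convergence Monte-Carlo studies
# ---------------------------------------------------------------------------

STUDY_REPERTOIRE_SIZE = 300
STUDY_N_RANDOM = 100


def study_cohort_config(seed: int, mode: str) -> CohortConfig:
    """Single-patient two-joint Treg cohort used by the operating-characteristic studies."""
    return CohortConfig(
        n_patients=1,
        compartments=("SF_LEFT", "SF_RIGHT"),
        subsets=("TREG",),
        visits=1,
        repertoire_size=STUDY_REPERTOIRE_SIZE,
        selection_mode=mode,
        planted_shared=(PlantedSharedSpec(30, rank_band=(1, 70)),),
        planted_clusters=(PlantedClusterSpec(6, 8),),
        seed=seed,
    )


def _patient_network_test(reps, model, n_random: int, seed: int):
    left, right = reps
    pairs = [(c.junction_aa, LABEL_LEFT) for c in left.clonotypes if c.productive]
    pairs += [(c.junction_aa, LABEL_RIGHT) for c in right.clonotypes if c.productive]
    cfg = NetworkConfig(n_random=n_random, seed=seed)
    net = build_network(pairs, cfg)
    stats = cluster_statistics(net, cfg.top_c)
    sizes = (len(left.junction_set(productive_only=True)), len(right.junction_set(productive_only=True)))
    comp = compare_to_random(stats, model, sizes, cfg)
    patient_med = float(np.median([s.purity for s in stats]))
    random_med = float(comp.random_stats["purity"].median())
    return comp.purity_test.p_value, patient_med, random_med


def antigen_network_detection(
    n_seeds: int = 25,
    base_seed: int = 0,
    n_random: int = STUDY_N_RANDOM,
    model: RecombinationModel | None = None,
) -> dict:
    """Fraction of planted-family cohorts where patient purity < random, MW p < 0.05."""
    model = model or default_model()
    hits = 0
    for i in range(n_seeds):
        reps, _ = generate_cohort(study_cohort_config(_sub_seed(base_seed, 41, i), "ANTIGEN"), model)
        p, patient_med, random_med = _patient_network_test(reps, model, n_random, _sub_seed(base_seed, 42, i))
        hits += int(p < 0.05 and patient_med < random_med)
    return {"n_seeds": n_seeds, "detection_rate": hits / n_seeds}


def neutral_network_false_positive_rate(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_random: int = STUDY_N_RANDOM,
    model: RecombinationModel | None = None,
) -> dict:
    """Two-sided rejection rate when the 'patient' repertoires carry no planted structure."""
    model = model or default_model()
    fp = 0
    for i in range(n_seeds):
        reps, _ = generate_cohort(study_cohort_config(_sub_seed(base_seed, 51, i), "NEUTRAL"), model)
        p, _, _ = _patient_network_test(reps, model, n_random, _sub_seed(base_seed, 52, i))
        fp += int(p < 0.05)
    return {"n_seeds": n_seeds, "false_positive_rate": fp / n_seeds}


def convergence_dichotomy(
    n_seeds: int = 50,
    base_seed: int = 0,
    model: RecombinationModel | None = None,
) -> dict:
    """NEUTRAL: positive non-shared frequency-p_gen correlation detected (p < 0.05).
    ANTIGEN: shared-group 95% CI covers zero."""
    model = model or default_model()
    neutral_hits = 0
    cover = 0
    for i in range(n_seeds):
        reps, _ = generate_cohort(study_cohort_config(_sub_seed(base_seed, 61, i), "NEUTRAL"), model)
        res = correlate_freq_pgen(shared_nonshared_table(reps[0], reps[1], model))[NON_SHARED]
        neutral_hits += int(res.flag is None and res.rho > 0 and res.p_value < 0.05)

        reps, _ = generate_cohort(study_cohort_config(_sub_seed(base_seed, 62, i), "ANTIGEN"), model)
        res = correlate_freq_pgen(shared_nonshared_table(reps[0], reps[1], model))[SHARED]
        cover += int(res.flag is None and res.ci_low <= 0.0 <= res.ci_high)
    return {
        "n_seeds": n_seeds,
        "neutral_nonshared_detection_rate": neutral_hits / n_seeds,
        "antigen_shared_ci_zero_coverage": cover / n_seeds,
    }


def overlap_identity_benchmark(n_cases: int = 1000, seed: int = 5) -> dict:
    """Exact overlap identities on randomized repertoires: violations counted."""
    from .io import repertoire_from_counts
    from .overlap import jaccard_matrix, top_n_intersection, venn_counts

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    pool = np.array(["".join(rng.choice(alphabet, size=6)) for _ in range(60)])
    violations = 0

    def random_rep(sample_id):
        keys = rng.choice(pool, size=rng.integers(3, 15), replace=False)
        return repertoire_from_counts(
            [(k, None, None, int(rng.integers(1, 50))) for k in keys],
            sample_id=sample_id, patient="P", compartment="SF_LEFT", subset="TREG", visit=0,
        )

    per_round = 4  # identities checked per random draw
    for _ in range(max(1, n_cases // per_round)):
        a, b, c = (random_rep(s) for s in "abc")
        mat = jaccard_matrix([a, b]).values
        violations += int(not (mat[0, 0] == mat[1, 1] == 1.0))
        violations += int(not (mat[0, 1] == mat[1, 0] and 0.0 <= mat[0, 1] <= 1.0))
        same = top_n_intersection(a, a, [len(a)])
        violations += int(same.percent_overlap[-1] != 100.0)
        regions = venn_counts([a, b, c], top_n=8)
        union = set()
        for r in (a, b, c):
            ranked = sorted(r.junction_counts().items(), key=lambda kv: (-kv[1], kv[0]))[:8]
            union |= {j for j, _ in ranked}
        violations += int(sum(regions.values()) != len(union))
    return {"n_cases": n_cases, "violations": violations}


# ---------------------------------------------------------------------------
# Closed forms and statistics oracles
# ---------------------------------------------------------------------------

def diversity_closed_forms(seed: int = 7) -> dict:
    """Rarefaction closed forms and Monte-Carlo Shannon vs exhaustive enumeration."""
    singleton = AbundanceVector((1,) * 8)
    singleton_dev = max(abs(rarefied_richness(singleton, m) - m) for m in range(1, 9))
    richness_21 = rarefied_richness(AbundanceVector((2, 1)), 2)
    b = 4000
    shannon_21 = rarefy_shannon(AbundanceVector((2, 1)), [2], b_reps=b, seed=seed).estimates[0]
    # exhaustive enumeration: subsets {AA} (H=0) and {AB} twice (H=ln 2)
    exact = math.exp(2 / 3 * math.log(2))
    return {
        "singleton_max_abs_deviation": singleton_dev,
        "richness_counts_2_1_at_m2": richness_21,
        "shannon_counts_2_1_at_m2": shannon_21,
        "shannon_enumeration_value": exact,
        "shannon_abs_error": abs(shannon_21 - exact),
        "b_reps": b,
    }


def _enumerated_mw_p(a, b) -> float:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    mu = na * len(b) / 2
    obs = ranks[:na].sum() - na * (na + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        total += 1
        u = sum(ranks[i] for i in idx) - na * (na + 1) / 2
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def _enumerated_spearman_midp(x, y) -> float:
    obs = abs(sps.spearmanr(x, y).statistic)
    more = ties = total = 0
    for perm in itertools.permutations(y):
        total += 1
        r = abs(sps.spearmanr(x, perm).statistic)
        if r > obs + 1e-9:
            more += 1
        elif r >= obs - 1e-9:
            ties += 1
    return (more + 0.5 * ties) / total


def stats_oracle_benchmark(seed: int = 3, n_cases: int = 10) -> dict:
    """Exact Mann-Whitney p vs enumeration; Spearman t-approx p vs permutation mid-p."""
    rng = np.random.default_rng(seed)
    mw_err = 0.0
    for _ in range(n_cases):
        na, nb = rng.integers(2, 9, size=2)
        a, b = rng.normal(size=na), rng.normal(size=nb)
        mw_err = max(mw_err, abs(mann_whitney_u(a, b, method="exact").p_value - _enumerated_mw_p(a, b)))
    sp_err = 0.0
    for _ in range(n_cases):
        x, y = rng.normal(size=5), rng.normal(size=5)
        sp_err = max(sp_err, abs(spearman_correlation(x, y).p_value - _enumerated_spearman_midp(x, y)))
    return {"n_cases": n_cases, "mw_exact_max_abs_error": mw_err, "spearman_t_vs_exact_max_abs_dev": sp_err}


# ---------------------------------------------------------------------------
# End-to-end reproducibility
# ---------------------------------------------------------------------------

def _tree_bytes(root: str) -> dict[str, bytes]:
    out = {}
    for dirpath, _dirs, files in os.walk(root):
        for f in sorted(files):
            p = os.path.join(dirpath, f)
            with open(p, "rb") as fh:
                out[os.path.relpath(p, root)] = fh.read()
    return out


def pipeline_reproducibility(seed: int = 1, workdir: str | None = None) -> dict:
    """Run the full default pipeline twice; byte-compare every output file."""
    from .pipeline import RunConfig, run_all

    base = workdir or tempfile.mkdtemp(prefix="tcrshare_accept_")
    trees = []
    elapsed = 0.0
    for name in ("run_a", "run_b"):
        out = os.path.join(base, name)
        t0 = time.time()
        run_all(RunConfig(seed=seed, outdir=out))
        elapsed = time.time() - t0  # keep the second (cache-warm) run's time
        trees.append(_tree_bytes(out))
    identical = trees[0].keys() == trees[1].keys() and all(trees[0][k] == trees[1][k] for k in trees[0])
    return {
        "byte_identical": float(identical),
        "n_output_files": len(trees[0]),
        "elapsed_seconds": elapsed,
    }
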