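"""Synthetic cohort generator: determinism, planted structure, clone-size law."""

import numpy as np
import pytest

from tcrshare.cohort import (
    CohortConfig,
    PlantedClusterSpec,
    PlantedSharedSpec,
    generate_cohort,
    generate_random_repertoire,
    _zipf_counts,
)
from tcrshare.errors import GenerationError, ValidationError
from tcrshare.io import write_clonotype_table


def small_cfg(**kw):
    base = dict(
        n_patients=1, compartments=("SF_LEFT", "SF_RIGHT"), subsets=("TREG",),
        visits=1, repertoire_size=200,
        planted_shared=(PlantedSharedSpec(10, rank_band=(1, 40)),),
        planted_clusters=(PlantedClusterSpec(2, 6),),
        seed=5,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self, trb_model, tmp_path):
        files = []
        for run in (0, 1):
            reps, _ = generate_cohort(small_cfg(), trb_model)
            path = tmp_path / f"run{run}.tsv"
            write_clonotype_table(reps[0], path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_different_seed_differs(self, trb_model):
        a, _ = generate_cohort(small_cfg(seed=1), trb_model)
        b, _ = generate_cohort(small_cfg(seed=2), trb_model)
        assert a[0].junction_set() != b[0].junction_set()


class TestPlantedStructure:
    def test_shared_clones_present_in_both_compartments(self, trb_model):
        reps, truth = generate_cohort(small_cfg(), trb_model)
        shared = truth.shared_for("P1", "TREG")
        assert len(shared) == 20  # 10 × treg multiplier 2.0
        for rep in reps:
            assert shared <= rep.junction_set()

    def test_planted_clones_in_configured_rank_band(self, trb_model):
        reps, truth = generate_cohort(small_cfg(), trb_model)
        shared = truth.shared_for("P1", "TREG")
        for rep in reps:
            ranked = [c.junction_aa for c in rep.clonotypes]  # already count-sorted
            for j in shared:
                assert ranked.index(j) < 100  # band (1, 40) plus multinomial count jitter
        # families recoverable: every member is present somewhere
        for members in truth.cluster_families.values():
            present = set().union(*(r.junction_set() for r in reps))
            assert set(members) <= present

    def test_persistence_across_visits(self, trb_model):
        reps, truth = generate_cohort(small_cfg(visits=2), trb_model)
        shared = truth.shared_for("P1", "TREG")
        for rep in reps:
            assert shared <= rep.junction_set()

    def test_neutral_mode_plants_nothing(self, trb_model):
        _, truth = generate_cohort(small_cfg(selection_mode="NEUTRAL"), trb_model)
        assert truth.shared_clone_keys == {} and truth.cluster_families == {}

    def test_treg_multiplier_asymmetry(self, trb_model):
        cfg = small_cfg(subsets=("TREG", "NON_TREG"), planted_clusters=())
        _, truth = generate_cohort(cfg, trb_model)
        assert len(truth.shared_for("P1", "TREG")) > len(truth.shared_for("P1", "NON_TREG"))


class TestCloneSizeLaw:
    def test_zipf_counts_shape(self):
        counts = _zipf_counts(100, 1.5, 5000, np.random.default_rng(0))
        assert counts[0] == counts.max()
        assert counts.min() >= 1
        # top clone exceeds median by at least the factor implied by alpha
        assert counts[0] / np.median(counts) >= (50 / 1) ** 1.5 / 10

    def test_heavy_tail_in_emitted_repertoire(self, trb_model):
        reps, _ = generate_cohort(small_cfg(), trb_model)
        freqs = sorted((c.frequency for c in reps[0].clonotypes), reverse=True)
        assert freqs[0] > 20 * np.median(freqs)


class TestPlantedSharingExceedsNeutral:
    def test_jaccard_monte_carlo(self, trb_model):
        """Planted-sharing cohorts overlap more than neutral cohorts of the same size."""
        from tcrshare.overlap import jaccard_index
        from tcrshare.stats import mann_whitney_u

        def jaccards(mode, offset):
            out = []
            for seed in range(25):
                cfg = small_cfg(selection_mode=mode, planted_clusters=(), repertoire_size=120,
                                planted_shared=(PlantedSharedSpec(10, rank_band=(1, 30)),),
                                seed=1000 * offset + seed)
                reps, _ = generate_cohort(cfg, trb_model)
                out.append(jaccard_index(reps[0].junction_set(), reps[1].junction_set()))
            return out

        planted = jaccards("ANTIGEN", 1)
        neutral = jaccards("NEUTRAL", 2)
        res = mann_whitney_u(planted, neutral)
        assert np.median(planted) > np.median(neutral)
        assert res.p_value / 2 < 0.05  # one-sided


class TestNeutralCoupling:
    def test_frequency_pgen_correlation_positive_over_replicates(self, trb_model):
        from tcrshare.stats import spearman_correlation
        from tcrshare.vdj import pgen_aa_many

        rhos = []
        for seed in range(5):
            cfg = small_cfg(selection_mode="NEUTRAL", planted_shared=(), planted_clusters=(), seed=seed)
            reps, _ = generate_cohort(cfg, trb_model)
            freqs = {c.junction_aa: c.frequency for c in reps[0].clonotypes}
            junctions = sorted(freqs)
            pg = pgen_aa_many(trb_model, junctions)
            rhos.append(spearman_correlation([freqs[j] for j in junctions], pg).statistic)
        assert np.mean(rhos) > 0.2


class TestRandomRepertoire:
    def test_exact_size_unique_count_one(self, trb_model):
        rep = generate_random_repertoire(trb_model, 50, seed=3)
        assert len(rep) == 50
        assert all(c.count == 1 for c in rep.clonotypes)

    def test_seed_determinism(self, trb_model):
        a = generate_random_repertoire(trb_model, 30, seed=9)
        b = generate_random_repertoire(trb_model, 30, seed=9)
        assert a.clonotypes == b.clonotypes

    def test_support_exhaustion_fails(self, m1):
        with pytest.raises(GenerationError):
            generate_random_repertoire(m1, 2, seed=0)

    def test_size_one(self, m1):
        rep = generate_random_repertoire(m1, 1, seed=0)
        assert len(rep) == 1


class TestConfigValidation:
    def test_alpha_bound(self):
        with pytest.raises(ValidationError):
            small_cfg(alpha=0.9)

    def test_planted_exceeding_repertoire(self):
        with pytest.raises(ValidationError):
            small_cfg(repertoire_size=20)

    def test_family_too_short_for_kmer_rule(self, trb_model):
        cfg = small_cfg(planted_clusters=(PlantedClusterSpec(1, 4, length_range=(9, 10)),))
        with pytest.raises(GenerationError):
            generate_cohort(cfg, trb_model)
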