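"""Generative model: exact p_gen vs exhaustive enumeration, sampling laws."""

import numpy as np
import pytest

from tcrshare._codons import translate
from tcrshare.errors import ValidationError
from tcrshare.vdj import (
    RecombinationModel,
    Segment,
    count_scenarios,
    enumerate_pgen_aa_oracle,
    enumerate_pgen_oracle,
    pgen_aa,
    pgen_aa_python,
    pgen_nt,
    sample_junctions,
)


class TestPgenNt:
    def test_degenerate_model_point_mass(self, m1):
        assert pgen_nt(m1, "TGTTTT").pgen == 1.0
        assert pgen_nt(m1, "TGTTTA").pgen == 0.0

    def test_single_insertion_scenario(self, m2):
        # one scenario: ins length 1 (p=0.5) with nucleotide A (p=0.25)
        assert pgen_nt(m2, "TGTATTT").pgen == pytest.approx(0.125, abs=1e-15)

    def test_two_scenarios_sum(self, m3):
        # (del=0, ins=0): 0.25 plus (del=1, ins="T"): 0.0625
        assert pgen_nt(m3, "TGTTTT").pgen == pytest.approx(0.3125, abs=1e-15)

    def test_invalid_alphabet_rejected(self, m1):
        with pytest.raises(ValidationError):
            pgen_nt(m1, "TGUTTT")

    def test_matches_enumeration_oracle_on_all_toys(self, toy_models):
        for model in toy_models:
            oracle = enumerate_pgen_oracle(model)
            assert sum(oracle.values()) == pytest.approx(1.0, abs=1e-9)
            for nt, p in oracle.items():
                assert pgen_nt(model, nt).pgen == pytest.approx(p, abs=1e-12)


class TestPgenAa:
    def test_degenerate_model(self, m1):
        assert pgen_aa(m1, "CF").pgen == 1.0

    def test_aa_dominates_every_coding_nt(self, toy_models):
        for model in toy_models:
            for nt, _ in list(enumerate_pgen_oracle(model).items())[:50]:
                if len(nt) % 3:
                    continue
                aa = translate(nt)
                if "*" in aa:
                    continue
                assert pgen_aa(model, aa).pgen >= pgen_nt(model, nt).pgen - 1e-15

    @pytest.mark.parametrize("backend", ["python", "numba"])
    def test_matches_codon_grouped_oracle(self, toy_models, backend):
        for model in toy_models:
            oracle = enumerate_pgen_aa_oracle(model)
            for aa, p in oracle.items():
                if backend == "python":
                    value = pgen_aa_python(model, aa)
                else:
                    value = pgen_aa(model, aa, backend="numba").pgen
                assert value == pytest.approx(p, abs=1e-12), (model.name, aa)

    def test_backends_agree_on_trb_model(self, trb_model):
        draws = sample_junctions(trb_model, 30, seed=7, productive_only=True)
        for _nt, aa in draws:
            assert pgen_aa(trb_model, aa, backend="numba").pgen == pytest.approx(
                pgen_aa_python(trb_model, aa), rel=1e-12
            )

    def test_insertion_mass_shift_monotonicity(self, m2):
        # moving insertion-length mass to longer insertions never increases
        # the p_gen of the zero-insertion junction
        base = pgen_nt(m2, "TGTTTT").pgen
        shifted = RecombinationModel(
            m2.v_segments, m2.j_segments, [1.0], [1.0], [0.25, 0.75], m2.insertion_nt_probs
        )
        assert pgen_nt(shifted, "TGTTTT").pgen <= base


class TestEnumerationOracle:
    def test_m1_point_mass(self, m1):
        assert enumerate_pgen_oracle(m1) == {"TGTTTT": 1.0}

    def test_m2_support_is_five_sequences(self, m2):
        oracle = enumerate_pgen_oracle(m2)
        assert len(oracle) == 5
        assert sum(oracle.values()) == pytest.approx(1.0, abs=1e-12)

    def test_scenario_cap_refusal(self, trb_model):
        assert count_scenarios(trb_model) > 10**6
        with pytest.raises(ValidationError, match="scenarios"):
            enumerate_pgen_oracle(trb_model)


class TestSampling:
    def test_zero_draws(self, m2):
        assert sample_junctions(m2, 0, seed=1) == []

    def test_seed_determinism(self, trb_model):
        a = sample_junctions(trb_model, 200, seed=42, productive_only=True)
        b = sample_junctions(trb_model, 200, seed=42, productive_only=True)
        assert a == b

    def test_degenerate_model_always_same_junction(self, m1):
        for nt, aa in sample_junctions(m1, 20, seed=0):
            assert nt == "TGTTTT" and aa == "CF"

    def test_translation_consistency(self, trb_model):
        for nt, aa in sample_junctions(trb_model, 300, seed=3, productive_only=True):
            assert len(nt) == 3 * len(aa)
            assert translate(nt) == aa
            assert "*" not in aa

    def test_unproductive_model_fails_after_capped_redraws(self):
        # junction length 3 + 0 + 2 = 5, never a multiple of 3: no productive draw
        model = RecombinationModel(
            [Segment("V1", "TGT", 1.0)], [Segment("J1", "TT", 1.0)],
            [1.0], [1.0], [1.0], np.full(4, 0.25),
        )
        from tcrshare.errors import GenerationError

        with pytest.raises(GenerationError, match="productive"):
            sample_junctions(model, 5, seed=0, productive_only=True, max_rounds=5)

    def test_empirical_frequencies_match_oracle(self, m2):
        # 1e5 draws: each support junction within 3 binomial SE of its probability
        oracle = enumerate_pgen_oracle(m2)
        n = 100_000
        draws = sample_junctions(m2, n, seed=11)
        counts = {}
        for nt, _ in draws:
            counts[nt] = counts.get(nt, 0) + 1
        for nt, p in oracle.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(nt, 0) / n - p) <= 3 * se


class TestModelValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            RecombinationModel(
                [Segment("V1", "TGT", 0.9)], [Segment("J1", "TTT", 1.0)],
                [1.0], [1.0], [1.0], np.full(4, 0.25),
            )

    def test_deletion_support_bounded_by_segment(self):
        with pytest.raises(ValidationError, match="deletion support"):
            RecombinationModel(
                [Segment("V1", "TGT", 1.0)], [Segment("J1", "TTT", 1.0)],
                [0.5, 0.2, 0.2, 0.05, 0.05], [1.0], [1.0], np.full(4, 0.25),
            )

    def test_yaml_round_trip(self, trb_model, tmp_path):
        path = tmp_path / "model.yaml"
        trb_model.to_yaml(path)
        again = RecombinationModel.from_yaml(path)
        assert again.to_dict() == trb_model.to_dict()
        assert again.fingerprint() == trb_model.fingerprint()
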