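"""Overlap statistics: exact identities plus randomized property tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrshare.errors import ValidationError
from tcrshare.io import repertoire_from_counts
from tcrshare.overlap import (
    classify_sharing,
    clonal_proportion_summary,
    jaccard_matrix,
    paired_frequency_table,
    top_n_intersection,
    venn_counts,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rep(counts: dict[str, int], sample_id="s", compartment="SF_LEFT", visit=0):
    return repertoire_from_counts(
        [(j, None, None, c) for j, c in counts.items()],
        sample_id=sample_id, patient="P1", compartment=compartment, subset="TREG", visit=visit,
    )


junctions = st.text(alphabet=AA, min_size=4, max_size=12)
count_maps = st.dictionaries(junctions, st.integers(min_value=1, max_value=500), min_size=1, max_size=40)


class TestClonalProportions:
    def test_two_singletons_all_mass_in_first_bin(self):
        table = clonal_proportion_summary(rep({"CASSA": 1, "CASSG": 1}))
        assert table.set_index("bin")["proportion"]["1"] == pytest.approx(1.0)

    def test_hyperexpanded_bin_mass(self):
        table = clonal_proportion_summary(rep({"CASSA": 100, "CASSG": 1}))
        by_bin = table.set_index("bin")["proportion"]
        assert by_bin[">=100"] == pytest.approx(100 / 101)
        assert by_bin["1"] == pytest.approx(1 / 101)

    @given(count_maps)
    @settings(max_examples=60, deadline=None)
    def test_proportions_sum_to_one(self, counts):
        table = clonal_proportion_summary(rep(counts))
        assert table["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValidationError):
            clonal_proportion_summary(rep({"CASSA": 1}), bin_edges=(1, 10, 5))


class TestTopN:
    def test_identical_repertoires_always_100(self):
        a = rep({"CASSA": 5, "CASSG": 3, "CASSC": 1})
        curve = top_n_intersection(a, a, [1, 2, 3])
        assert curve.percent_overlap == (100.0, 100.0, 100.0)

    def test_disjoint_repertoires_zero(self):
        a = rep({"CASSA": 5, "CASSG": 3})
        b = rep({"CAWSA": 5, "CAWSG": 3}, sample_id="t")
        curve = top_n_intersection(a, b, [1, 2])
        assert curve.percent_overlap == (0.0, 0.0)

    def test_two_of_three_shared(self):
        a = rep({"W" * 4: 9, "Y" * 4: 8, "K" * 4: 7})
        b = rep({"W" * 4: 9, "Q" * 4: 8, "K" * 4: 7}, sample_id="t")
        curve = top_n_intersection(a, b, [3])
        assert curve.percent_overlap[0] == pytest.approx(100 * 2 / 3)

    def test_oversized_n_dropped(self):
        a = rep({"CASSA": 2, "CASSG": 1})
        curve = top_n_intersection(a, a, [1, 2, 50])
        assert curve.n_values == (1, 2)

    @given(count_maps, count_maps)
    @settings(max_examples=60, deadline=None)
    def test_full_size_identical_key_sets_is_100(self, counts, _ignored):
        # same keys, different counts: at n = |A| = |B| the overlap must be 100%
        other = {j: (c % 7) + 1 for j, c in counts.items()}
        a, b = rep(counts), rep(other, sample_id="t")
        curve = top_n_intersection(a, b, [len(counts)])
        assert curve.percent_overlap[-1] == pytest.approx(100.0)


class TestJaccard:
    def test_worked_example(self):
        a = rep({"A" * 4: 1, "C" * 4: 1, "D" * 4: 1})
        b = rep({"C" * 4: 1, "D" * 4: 1, "E" * 4: 1}, sample_id="t")
        mat = jaccard_matrix([a, b])
        assert mat.values[0, 1] == pytest.approx(0.5)

    @given(count_maps, count_maps)
    @settings(max_examples=80, deadline=None)
    def test_symmetry_diagonal_and_range(self, ca, cb):
        a, b = rep(ca, sample_id="a"), rep(cb, sample_id="b")
        mat = jaccard_matrix([a, b]).values
        assert mat[0, 0] == mat[1, 1] == 1.0
        assert mat[0, 1] == mat[1, 0]
        assert 0.0 <= mat[0, 1] <= 1.0

    def test_empty_repertoire_not_constructible(self):
        with pytest.raises(ValidationError):
            rep({})


class TestSharingClasses:
    def test_three_sample_labels(self):
        pb = rep({"CASSA": 1, "CASSG": 1}, sample_id="pb", compartment="PB")
        lf = rep({"CASSA": 1, "CASSC": 1}, sample_id="lf")
        rt = rep({"CASSA": 1, "CASSG": 1, "CASSD": 1}, sample_id="rt", compartment="SF_RIGHT")
        classes = classify_sharing([pb, lf, rt]).set_index("junction_aa")["n_samples_present"]
        assert classes["CASSA"] == 3
        assert classes["CASSG"] == 2
        assert classes["CASSC"] == 1

    @given(count_maps, count_maps)
    @settings(max_examples=60, deadline=None)
    def test_partition_of_union(self, ca, cb):
        a, b = rep(ca, sample_id="a"), rep(cb, sample_id="b")
        classes = classify_sharing([a, b])
        assert len(classes) == len(set(ca) | set(cb))


class TestPairedFrequencies:
    def test_exclusive_clone_row(self):
        a = rep({"CASSA": 1, "CASSG": 4})
        b = rep({"CASSG": 1}, sample_id="t", compartment="SF_RIGHT")
        table = paired_frequency_table(a, b).set_index("junction_aa")
        assert table.loc["CASSA", "freq_a"] == pytest.approx(0.2)
        assert table.loc["CASSA", "freq_b"] == 0.0
        assert table.loc["CASSA", "n_samples_present"] == 1

    @given(count_maps, count_maps)
    @settings(max_examples=60, deadline=None)
    def test_row_count_and_frequency_fidelity(self, ca, cb):
        a, b = rep(ca, sample_id="a"), rep(cb, sample_id="b")
        table = paired_frequency_table(a, b)
        assert len(table) == len(set(ca) | set(cb))
        fa = a.junction_frequencies()
        for row in table.itertuples():
            assert row.freq_a == pytest.approx(fa.get(row.junction_aa, 0.0))


class TestVenn:
    def test_pairwise_regions(self):
        a = rep({"CASSA": 2, "CASSG": 1})
        b = rep({"CASSG": 2, "CASSC": 1}, sample_id="t")
        regions = venn_counts([a, b], top_n=2)
        assert regions[("s",)] == 1 and regions[("t",)] == 1 and regions[("s", "t")] == 1

    def test_identical_tops_only_full_intersection(self):
        a = rep({"CASSA": 2, "CASSG": 1})
        b = rep({"CASSA": 5, "CASSG": 9}, sample_id="t")
        regions = venn_counts([a, b], top_n=2)
        assert regions[("s", "t")] == 2
        assert regions[("s",)] == regions[("t",)] == 0

    @given(count_maps, count_maps, count_maps)
    @settings(max_examples=60, deadline=None)
    def test_region_conservation(self, ca, cb, cc):
        reps = [rep(c, sample_id=s) for c, s in ((ca, "a"), (cb, "b"), (cc, "c"))]
        top = 10
        regions = venn_counts(reps, top_n=top)
        union = set()
        for r in reps:
            ranked = sorted(r.junction_counts().items(), key=lambda kv: (-kv[1], kv[0]))[:top]
            union |= {j for j, _ in ranked}
        assert sum(regions.values()) == len(union)
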