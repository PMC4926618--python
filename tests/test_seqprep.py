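import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodiv.align import Scoring, align_pair
from barcodiv.errors import DataError
from barcodiv.records import DistanceMatrix, ReferenceLibrary, SequenceRecord
from barcodiv.seqprep import (cluster_by_threshold, dereplicate,
                              distance_matrix, orient_sequences,
                              pairwise_distance, progressive_align,
                              recruit_references, trim_to_marker)

SC = Scoring()


def brute_force_best_score(a: str, b: str) -> float:
    """Enumerate every global alignment (as a monotone path) and score it
    with affine gaps; exponential, for tiny inputs only."""
    best = -np.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = SC.match if a[i] == b[j] else SC.mismatch
            rec(i + 1, j + 1, "D", score + s)
        if i < len(a):
            gap = SC.gap_extend if prev == "V" else SC.gap_open
            rec(i + 1, j, "V", score + gap)
        if j < len(b):
            gap = SC.gap_extend if prev == "H" else SC.gap_open
            rec(i, j + 1, "H", score + gap)

    rec(0, 0, "", 0.0)
    return best


class TestPairwiseDistance:
    def test_hand_counted_p_distance(self):
        assert pairwise_distance("ACGT", "ACGA") == pytest.approx(0.25)

    @pytest.mark.parametrize("model", ["p", "jc", "k2p"])
    def test_identical_sequences_zero(self, model):
        assert pairwise_distance("ACGTACGT", "ACGTACGT",
                                 model=model) == pytest.approx(0.0)

    def test_jc_closed_form_at_quarter(self):
        # p = 0.25 -> -0.75 ln(2/3)
        d = pairwise_distance("AAAA", "AAAC", model="jc")
        assert d == pytest.approx(-0.75 * math.log(2 / 3), abs=1e-10)

    def test_jc_saturation_sentinel(self):
        assert np.isinf(pairwise_distance("AAAA", "CCCC", model="jc"))

    def test_ambiguity_sites_excluded(self):
        # N and gap columns do not count as compared sites
        assert pairwise_distance("ACGN", "ACGT") == pytest.approx(0.0)
        assert pairwise_distance("AC-T", "ACGT") == pytest.approx(0.0)

    def test_zero_comparable_sites_error(self):
        with pytest.raises(DataError):
            pairwise_distance("NNNN", "ACGT")

    @pytest.mark.parametrize("seed", range(8))
    def test_corrected_distances_dominate_p(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(ch if rng.random() > 0.3
                    else rng.choice(list("ACGT")) for ch in a)
        p = pairwise_distance(a, b, model="p")
        if 0 < p < 0.74:
            assert pairwise_distance(a, b, model="jc") >= p
            assert pairwise_distance(a, b, model="k2p") >= p - 1e-12

    def test_unaligned_inputs_aligned_first(self):
        # 20 extra leading bases but same core: distance stays small
        core = "ACGTTGCAACGTACGTGGCC" * 4
        assert pairwise_distance("TTTTT" + core, core,
                                 aligned=False) == pytest.approx(0.0)


class TestAlignment:
    @pytest.mark.parametrize("a,b", [
        ("ACGT", "AGT"), ("ACGT", "ACGT"), ("AAAA", "AACA"),
        ("ACGTA", "CTA"), ("AC", "ACGTT"),
    ])
    def test_pairwise_matches_enumeration_oracle(self, a, b):
        _, _, score = align_pair(a, b)
        assert score == pytest.approx(brute_force_best_score(a, b))

    def test_degapping_recovers_inputs(self, small_survey):
        seqs = small_survey.records[:6]
        aln = progressive_align(seqs)
        assert len({len(r.bases) for r in aln}) == 1
        for before, after in zip(seqs, aln):
            assert after.bases.replace("-", "") == before.bases
            assert after.id == before.id

    def test_identical_sequences_align_gap_free(self):
        seqs = [SequenceRecord(id=f"s{i}", bases="ACGTACGT")
                for i in range(3)]
        aln = progressive_align(seqs)
        assert all("-" not in r.bases for r in aln)

    def test_single_sequence_returned_unchanged(self):
        seqs = [SequenceRecord(id="s", bases="ACGT")]
        assert progressive_align(seqs) == seqs

    def test_total_residue_count_conserved(self, small_survey):
        # length-variable input must never be silently truncated
        seqs = [r.replace_bases(r.bases[: 200 + 17 * i])
                for i, r in enumerate(small_survey.records[:5])]
        aln = progressive_align(seqs)
        assert sum(len(r.bases.replace("-", "")) for r in aln) \
            == sum(len(r.bases) for r in seqs)


class TestOrientation:
    def test_reverse_complement_query_flipped(self, small_survey):
        refs = small_survey.records[:3]
        query = refs[0].reverse_complement().replace_bases(
            refs[0].reverse_complement().bases)
        query = SequenceRecord(id="q", bases=query.bases)
        oriented, report = orient_sequences([query], refs)
        assert report.iloc[0].flipped
        assert oriented[0].bases == refs[0].bases

    def test_in_frame_query_unchanged(self, small_survey):
        refs = small_survey.records[:3]
        query = SequenceRecord(id="q", bases=refs[1].bases)
        oriented, report = orient_sequences([query], refs)
        assert not report.iloc[0].flipped
        assert oriented[0].bases == refs[1].bases

    def test_palindromic_query_flagged_ambiguous(self):
        # reverse-complement-symmetric sequence: equidistant on both strands
        pal = "ACGT" * 10
        assert SequenceRecord(id="x", bases=pal).reverse_complement().bases \
            == pal
        refs = [SequenceRecord(id="r", bases="ACGT" * 10 + "ACGT")]
        oriented, report = orient_sequences(
            [SequenceRecord(id="q", bases=pal)], refs)
        assert report.iloc[0].ambiguous
        assert oriented[0].bases == pal


class TestTrim:
    def test_leading_bases_removed(self):
        anchor = SequenceRecord(id="anchor", bases="ACGTTGCAACGTACGTGGCC" * 6)
        query = SequenceRecord(id="q", bases="TTATTGCATTACAGGATACA"
                               + anchor.bases)
        trimmed, report = trim_to_marker([query], anchor)
        assert trimmed[0].bases == anchor.bases
        assert report.iloc[0].trimmed_bases == 20

    def test_contained_query_unchanged(self):
        anchor = SequenceRecord(id="anchor", bases="ACGTTGCAACGTACGTGGCC" * 6)
        inner = SequenceRecord(id="q", bases=anchor.bases[10:-10])
        trimmed, _ = trim_to_marker([inner], anchor)
        assert trimmed[0].bases == inner.bases

    def test_short_residual_dropped_with_warning(self):
        anchor = SequenceRecord(id="anchor", bases="ACGTTGCAACGTACGTGGCC" * 6)
        frag = SequenceRecord(id="q", bases=anchor.bases[:50])
        trimmed, report = trim_to_marker([frag], anchor, l_min=100)
        assert trimmed == []
        assert not report.iloc[0].kept


class TestDereplicate:
    def test_duplicates_collapse_to_smallest_id(self):
        seqs = [SequenceRecord(id="s2", bases="ACGT"),
                SequenceRecord(id="s1", bases="ACGT"),
                SequenceRecord(id="s3", bases="ACGA")]
        reps, mapping = dereplicate(seqs)
        assert {r.id for r in reps} == {"s1", "s3"}
        assert mapping == {"s1": "s1", "s2": "s1", "s3": "s3"}

    def test_distinct_input_identity_mapping(self, toy_records):
        reps, mapping = dereplicate(toy_records[1:])
        assert len(reps) == 2
        assert all(k == v for k, v in mapping.items())

    def test_empty_input(self):
        assert dereplicate([]) == ([], {})


class TestClustering:
    def test_component_trace(self):
        dm = DistanceMatrix(ids=("a1", "a2", "a3"),
                            values=np.array([[0, 0.02, 0.20],
                                             [0.02, 0, 0.21],
                                             [0.20, 0.21, 0]]))
        groups = cluster_by_threshold(dm, 0.05)
        assert [set(g.members) for g in groups] == [{"a1", "a2"}, {"a3"}]

    def test_vacuous_thresholds(self):
        vals = np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]])
        dm = DistanceMatrix(ids=("x", "y", "z"), values=vals)
        assert len(cluster_by_threshold(dm, 1.0)) == 1
        assert len(cluster_by_threshold(dm, 0.0)) == 3

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        m = rng.random((n, n)) * 0.3
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(ids=tuple(f"s{i}" for i in range(n)), values=m)
        lo, hi = sorted(rng.random(2) * 0.3)
        coarse = {frozenset(g.members) for g in cluster_by_threshold(dm, hi)}
        fine = cluster_by_threshold(dm, lo)
        for g in fine:
            assert any(set(g.members) <= big for big in coarse)


class TestRecruitment:
    def _library(self, survey):
        return ReferenceLibrary(
            records=list(survey.records[:8]),
            lineages={r.id: survey.lineages[r.id]
                      for r in survey.records[:8]})

    def test_vacuous_thresholds_recruit_everything(self, small_survey):
        lib = self._library(small_survey)
        queries = [SequenceRecord(id="q1", bases=lib.records[0].bases)]
        from barcodiv.seqprep import QueryGroup
        group = QueryGroup(group_id="g1", members=("q1",))
        out, log = recruit_references(group, queries, lib,
                                      d_max=np.inf, kappa_min=0.0)
        assert set(out.refs) == set(lib.ids)
        assert len(log) == len(lib)

    def test_distance_threshold_respected(self, small_survey):
        lib = self._library(small_survey)
        near = lib.records[0]
        queries = [SequenceRecord(id="q1", bases=near.bases)]
        from barcodiv.seqprep import QueryGroup
        group = QueryGroup(group_id="g1", members=("q1",))
        out, log = recruit_references(group, queries, lib, d_max=0.02)
        assert near.id in out.refs
        far = log[~log.reference.isin(out.refs)]
        assert (~far.distance_pass.fillna(False)
                | ~far.screen_pass).all()

    def test_no_recruit_flags_group(self, small_survey):
        lib = self._library(small_survey)
        alien = SequenceRecord(id="q1", bases="ATCGGCTA" * 40)
        from barcodiv.seqprep import QueryGroup
        group = QueryGroup(group_id="g1", members=("q1",))
        out, _ = recruit_references(group, [alien], lib, d_max=0.01)
        assert out.flagged == "unidentifiable"
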