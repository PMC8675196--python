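"""LOH scoring, mutation burden and feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihrdkit.cn_features import (
    CNSegment,
    CNSegmentProfile,
    GenomicFeatureVector,
    extract_features,
    loh_score,
    mutation_burden,
)
from ihrdkit.signatures import SignatureExposure

from _oracles import loh_score_units
from conftest import mb_profile


class TestLOHScore:
    def test_diploid_heterozygous_genome_scores_zero(self):
        prof = mb_profile(
            [("1", 0, 100, 2, 1), ("2", 0, 80, 3, 1)],
            {"1": 100, "2": 80},
        )
        assert loh_score(prof) == 0.0

    def test_single_event_hand_computed(self):
        # 20 Mb LOH on chrA, both chromosomes fully assessed (100 Mb each)
        prof = mb_profile(
            [("1", 0, 20, 1, 0), ("1", 20, 100, 2, 1), ("2", 0, 100, 2, 1)],
            {"1": 100, "2": 100},
        )
        assert loh_score(prof) == pytest.approx(20 / 200)

    def test_event_length_strictly_greater_than_15mb(self):
        base = [("2", 0, 100, 2, 1)]
        at_15 = mb_profile(base + [("1", 0, 15, 1, 0), ("1", 15, 100, 2, 1)],
                           {"1": 100, "2": 100})
        above = mb_profile(base + [("1", 0, 16, 1, 0), ("1", 16, 100, 2, 1)],
                           {"1": 100, "2": 100})
        assert loh_score(at_15) == 0.0
        assert loh_score(above) == pytest.approx(16 / 200)

    def test_homozygous_deletion_is_not_an_event(self):
        prof = mb_profile(
            [("1", 0, 20, 0, 0), ("1", 20, 100, 2, 1), ("2", 0, 100, 2, 1)],
            {"1": 100, "2": 100},
        )
        assert loh_score(prof) == 0.0

    def test_mostly_loh_chromosome_excluded_entirely(self):
        # 80 Mb event on a 100 Mb chromosome (>= 75%): dropped from both sides
        prof = mb_profile(
            [("1", 0, 80, 1, 0), ("1", 80, 100, 2, 1), ("2", 0, 100, 2, 1)],
            {"1": 100, "2": 100},
        )
        assert loh_score(prof) == 0.0

    def test_adjacent_loh_segments_merge_before_length_test(self):
        # two 10 Mb LOH segments, contiguous: one 20 Mb event
        prof = mb_profile(
            [("1", 0, 10, 1, 0), ("1", 10, 20, 2, 0), ("1", 20, 100, 2, 1),
             ("2", 0, 100, 2, 1)],
            {"1": 100, "2": 100},
        )
        assert loh_score(prof) == pytest.approx(20 / 200)

    def test_short_unassessed_gap_bridged_long_gap_not(self):
        pieces = [("1", 0, 10, 1, 0), ("1", 12, 22, 1, 0),  # 2 Mb gap
                  ("1", 22, 100, 2, 1), ("2", 0, 100, 2, 1)]
        bridged = mb_profile(pieces, {"1": 100, "2": 100})
        # numerator counts LOH bases only (20 Mb), denominator the assessed 198 Mb
        assert loh_score(bridged) == pytest.approx(20 / 198)
        far = [("1", 0, 10, 1, 0), ("1", 16, 26, 1, 0),  # 6 Mb gap: two 10 Mb runs
               ("1", 26, 100, 2, 1), ("2", 0, 100, 2, 1)]
        assert loh_score(mb_profile(far, {"1": 100, "2": 100})) == 0.0

    def test_heterozygous_segment_breaks_a_run(self):
        prof = mb_profile(
            [("1", 0, 10, 1, 0), ("1", 10, 11, 2, 1), ("1", 11, 21, 1, 0),
             ("1", 21, 100, 2, 1), ("2", 0, 100, 2, 1)],
            {"1": 100, "2": 100},
        )
        assert loh_score(prof) == 0.0

    def test_empty_and_fully_excluded_profiles_error(self):
        with pytest.raises(ValueError, match="no assessable"):
            loh_score(CNSegmentProfile("t", [], 2.0, 0.8, {"1": 10}))
        all_loh = mb_profile([("1", 0, 100, 1, 0)], {"1": 100})
        with pytest.raises(ValueError, match="exclusions"):
            loh_score(all_loh)

    def test_sex_chromosomes_ignored_by_default(self):
        prof = mb_profile(
            [("1", 0, 100, 2, 1), ("X", 0, 50, 1, 0), ("X", 50, 100, 2, 1)],
            {"1": 100, "X": 100},
        )
        assert loh_score(prof) == 0.0
        assert loh_score(prof, include_sex_chromosomes=True) > 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_split_invariance(self, data):
        """Splitting any segment into contiguous same-state pieces never
        changes the score."""
        prof = _random_mb_profile(np.random.default_rng(data.draw(st.integers(0, 10**6))))
        segs = sorted(prof.segments, key=lambda s: (s.chrom, s.start))
        i = data.draw(st.integers(0, len(segs) - 1))
        seg = segs[i]
        if seg.length >= 2_000_000:
            cut = seg.start + seg.length // 2
            pieces = [
                CNSegment(seg.chrom, seg.start, cut - 1, seg.total_cn, seg.minor_cn),
                CNSegment(seg.chrom, cut, seg.end, seg.total_cn, seg.minor_cn),
            ]
            split = CNSegmentProfile(
                prof.sample_id, [s for s in segs if s is not seg] + pieces,
                prof.ploidy, prof.cellularity, prof.chromosome_lengths,
            )
            assert loh_score(split) == pytest.approx(loh_score(prof), abs=1e-12)

    def test_agrees_with_base_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            prof = _random_mb_profile(rng)
            try:
                expected = loh_score_units(prof)
            except ValueError:
                with pytest.raises(ValueError):
                    loh_score(prof)
                continue
            assert loh_score(prof) == pytest.approx(expected, abs=1e-9)


def _random_mb_profile(rng) -> CNSegmentProfile:
    """Random small genome (<= 5 chromosomes) with 1 Mb-aligned segments,
    including unassessed gaps, homozygous deletions and near-whole-chromosome
    LOH edge cases."""
    n_chrom = int(rng.integers(2, 6))
    lengths = {}
    spec = []
    for ci in range(n_chrom):
        chrom = str(ci + 1)
        n_mb = int(rng.integers(30, 250))
        lengths[chrom] = n_mb
        if rng.random() < 0.15:  # exclusion-rule edge case
            ev = int(n_mb * rng.uniform(0.72, 0.95))
            spec += [(chrom, 0, ev, 1, 0), (chrom, ev, n_mb, 2, 1)]
            continue
        pos = 0
        while pos < n_mb:
            length = int(rng.integers(1, 41))
            end = min(pos + length, n_mb)
            r = rng.random()
            if r < 0.15:
                pass  # unassessed gap
            elif r < 0.25:
                spec.append((chrom, pos, end, 0, 0))  # homozygous deletion
            elif r < 0.55:
                total = int(rng.integers(1, 4))
                spec.append((chrom, pos, end, total, 0))  # LOH state
            else:
                total = int(rng.integers(2, 5))
                spec.append((chrom, pos, end, total, 1))
            pos = end
    return mb_profile(spec, lengths)


class TestMutationBurden:
    @pytest.mark.parametrize("n,mb,rate,hyper", [
        (600, 30.0, 20.0, True),     # boundary is inclusive
        (0, 30.0, 0.0, False),
        (104, 30.0, 104 / 30, False),
    ])
    def test_rate_and_hypermutation_flag(self, n, mb, rate, hyper):
        assert mutation_burden(n, mb) == (pytest.approx(rate), hyper)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mutation_burden(-1, 30.0)
        with pytest.raises(ValueError):
            mutation_burden(10, 0.0)


def _zero_exposure(sample_id="T", n=0):
    return SignatureExposure(
        sample_id, ("CSig3", "CSig8"), np.zeros(2), n, n > 50, False, False
    )


class TestExtractFeatures:
    def test_component_wise_against_independent_computation(self, small_sigs):
        prof = mb_profile(
            [("1", 0, 20, 1, 0), ("1", 20, 100, 2, 1), ("2", 0, 100, 2, 1)],
            {"1": 100, "2": 100}, ploidy=3.1,
        )
        exp = SignatureExposure(
            "T", ("CSig3", "CSig8"), np.array([0.3, 0.1]), 120, True, True, False
        )
        fv = extract_features(exp, prof)
        assert fv.as_array() == pytest.approx(
            [0.3, 0.1, 20 / 200, 120, 3.1, 3]
        )

    def test_pure_diploid_no_mutation_tumor(self):
        prof = mb_profile([("1", 0, 100, 2, 1), ("2", 0, 100, 2, 1)],
                          {"1": 100, "2": 100}, ploidy=2.0)
        fv = extract_features(_zero_exposure(), prof)
        assert fv.as_array() == pytest.approx([0, 0, 0, 0, 2.0, 2])

    def test_segment_order_invariance(self):
        spec = [("1", 0, 20, 1, 0), ("1", 20, 100, 2, 1), ("2", 0, 100, 2, 1)]
        a = mb_profile(spec, {"1": 100, "2": 100})
        b = mb_profile(spec[::-1], {"1": 100, "2": 100})
        assert extract_features(_zero_exposure(n=100), a).as_array() == pytest.approx(
            extract_features(_zero_exposure(n=100), b).as_array()
        )

    def test_sample_mismatch_rejected(self):
        prof = mb_profile([("1", 0, 100, 2, 1)], {"1": 100}, sample_id="OTHER")
        with pytest.raises(ValueError, match="mismatch"):
            extract_features(_zero_exposure("T"), prof)

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError, match="loh_score"):
            GenomicFeatureVector("t", 0.1, 0.1, 1.5, 10, 2.0, 5)
        with pytest.raises(ValueError, match="finite"):
            GenomicFeatureVector("t", 0.1, 0.1, 0.5, 10, float("nan"), 5)
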