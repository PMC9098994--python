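import math

import numpy as np
import pytest

from lohcna.cna_core import (
    AberrationState,
    call_profile,
    call_segment,
    classify_state,
    dichotomize_gii,
    genome_instability_index,
    ploidy_adjusted_cn,
    segment_loh,
)
from lohcna.io_formats import ProbeMap, Segment, SegmentProfile

from conftest import random_profile


def brute_force_gii(profile: SegmentProfile, probes: ProbeMap) -> float:
    """Independent probe-by-probe oracle for the genome instability index."""
    n_total = n_aberrant = 0
    for chrom in probes.chromosomes:
        for pos in probes.positions(chrom):
            for seg in profile.segments:
                if seg.chrom == chrom and seg.start <= pos <= seg.end:
                    n_total += 1
                    adj = round_half_away(seg.total_cn - profile.ploidy)
                    if adj != 0:
                        n_aberrant += 1
                    break
    return n_aberrant / n_total


def round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


class TestPloidyAdjustedCN:
    @pytest.mark.parametrize(
        "total,ploidy,expected",
        [(3, 2.0, 1), (2, 2.0, 0), (1, 3.6, -3), (2, 2.5, -1), (3, 2.5, 1),
         (0, 2.0, -2), (7, 2.2, 5)],
    )
    def test_rounding_half_away_from_zero(self, total, ploidy, expected):
        assert ploidy_adjusted_cn(total, ploidy) == expected

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            total = int(rng.integers(0, 9))
            ploidy = float(rng.uniform(0.5, 5.5))
            assert ploidy_adjusted_cn(total, ploidy) == round_half_away(total - ploidy)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ploidy_adjusted_cn(2, 0.0)
        with pytest.raises(ValueError):
            ploidy_adjusted_cn(-1, 2.0)


class TestClassifyState:
    @pytest.mark.parametrize(
        "adj,state",
        [(1, AberrationState.GAIN), (3, AberrationState.GAIN),
         (-1, AberrationState.LOSS), (-4, AberrationState.LOSS),
         (0, AberrationState.NEUTRAL)],
    )
    def test_thresholds(self, adj, state):
        assert classify_state(adj) is state

    def test_neutral_at_integer_ploidy(self):
        # a segment at exactly the (integer) ploidy is neutral
        for ploidy in (2.0, 3.0, 4.0):
            assert classify_state(ploidy_adjusted_cn(int(ploidy), ploidy)) is AberrationState.NEUTRAL


class TestSegmentLOH:
    @pytest.mark.parametrize("alleles,expected", [((2, 0), True), ((1, 1), False), ((0, 0), False)])
    def test_single_remaining_allele(self, alleles, expected):
        assert segment_loh(*alleles) is expected

    def test_any_major_count_with_zero_minor_is_loh(self):
        assert all(segment_loh(k, 0) for k in range(1, 12))

    def test_invalid_allele_order(self):
        with pytest.raises(ValueError):
            segment_loh(1, 2)


class TestCallSegment:
    def test_copy_neutral_loh(self):
        call = call_segment(Segment("chr1", 1, 100, 2, 0), ploidy=2.1)
        assert call.loh and call.adjusted_cn == 0 and call.copy_neutral_loh
        assert call.state is AberrationState.NEUTRAL

    def test_balanced_diploid_is_neutral(self):
        call = call_segment(Segment("chr1", 1, 100, 1, 1), ploidy=2.0)
        assert call.state is AberrationState.NEUTRAL and not call.loh

    def test_gained_loh_is_not_copy_neutral(self):
        call = call_segment(Segment("chr1", 1, 100, 3, 0), ploidy=2.0)
        assert call.state is AberrationState.GAIN and call.loh and not call.copy_neutral_loh

    def test_homozygous_deletion_flagged_not_loh(self):
        call = call_segment(Segment("chr1", 1, 100, 0, 0), ploidy=2.0)
        assert call.homozygous_deletion and not call.loh
        assert call.state is AberrationState.LOSS

    def test_exactly_one_state_per_segment(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            profile, _ = random_profile(rng)
            for call in call_profile(profile):
                assert call.state in (AberrationState.GAIN, AberrationState.NEUTRAL,
                                      AberrationState.LOSS)


class TestGII:
    def test_all_neutral_is_zero(self):
        p = SegmentProfile("S", 2.0, 0.9, (Segment("chr1", 1, 1000, 1, 1),))
        probes = ProbeMap({"chr1": [100, 500, 900]})
        assert genome_instability_index(p, probes).value == 0.0

    def test_all_aberrant_is_one(self):
        p = SegmentProfile("S", 2.0, 0.9, (Segment("chr1", 1, 1000, 3, 1),))
        probes = ProbeMap({"chr1": [100, 500, 900]})
        assert genome_instability_index(p, probes).value == 1.0

    def test_one_of_three_equal_segments_gained(self):
        segs = (
            Segment("chr1", 1, 1000, 2, 1),      # gain at ploidy 2
            Segment("chr1", 1001, 2000, 1, 1),
            Segment("chr1", 2001, 3000, 1, 1),
        )
        probes = ProbeMap({"chr1": np.arange(10, 3000, 10)})  # ~100 probes/segment
        gii = genome_instability_index(SegmentProfile("S", 2.0, 0.9, segs), probes)
        assert gii.value == pytest.approx(1 / 3, abs=0.01)

    def test_probes_outside_segments_excluded(self):
        p = SegmentProfile("S", 2.0, 0.9, (Segment("chr1", 1, 100, 3, 1),))
        probes = ProbeMap({"chr1": [50, 500, 900]})
        gii = genome_instability_index(p, probes)
        assert gii.n_probes_total == 1 and gii.value == 1.0

    def test_undefined_without_in_segment_probes(self):
        p = SegmentProfile("S", 2.0, 0.9, (Segment("chr1", 1, 100, 1, 1),))
        with pytest.raises(ValueError, match="undefined"):
            genome_instability_index(p, ProbeMap({"chr1": [500]}))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            profile, probes = random_profile(rng)
            try:
                gii = genome_instability_index(profile, probes)
            except ValueError:
                continue
            assert gii.value == pytest.approx(brute_force_gii(profile, probes))
            assert 0 <= gii.value <= 1
            checked += 1
        assert checked > 150

    def test_adding_gained_segment_never_decreases_gii(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            profile, probes = random_profile(rng)
            last = profile.segments[-1]
            extra = Segment(last.chrom, last.end + 1, last.end + 3000,
                            int(round(profile.ploidy)) + 2, 0)
            grown = SegmentProfile(
                profile.sample_id, profile.ploidy, profile.cellularity,
                profile.segments + (extra,),
            )
            probes2 = ProbeMap({
                last.chrom: np.union1d(probes.positions(last.chrom),
                                       [last.end + 100, last.end + 200])
            })
            try:
                before = genome_instability_index(profile, probes2).value
            except ValueError:
                continue
            after = genome_instability_index(grown, probes2).value
            assert after >= before


class TestDichotomize:
    def test_median_split(self):
        assert dichotomize_gii({"a": 0.1, "b": 0.5, "c": 0.9}) == {
            "a": "low", "b": "low", "c": "high"
        }

    def test_all_equal_are_low(self):
        assert set(dichotomize_gii({"a": 0.3, "b": 0.3, "c": 0.3}).values()) == {"low"}

    def test_two_samples(self):
        assert dichotomize_gii({"a": 0.2, "b": 0.8}) == {"a": "low", "b": "high"}

    def test_explicit_cutoff(self):
        assert dichotomize_gii({"a": 0.2, "b": 0.8}, cutoff=0.1) == {"a": "high", "b": "high"}

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_gii({"a": 0.5})
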