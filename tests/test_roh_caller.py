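"""Windowed ROH caller against an exhaustive brute-force reference."""

import numpy as np
import pytest

from rohcompare import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ROHParams,
    call_segments,
    snp_homozygosity_state,
    window_flags,
    write_hom_table,
)

from conftest import make_matrix
from oracles import brute_force_segments

SMALL = ROHParams(
    min_snp_final=10, min_kb_final=100, density_kb_per_snp=50,
    max_gap_kb=1000, window_snp=10, window_het=1, window_missing=2,
    window_threshold=0.05,
)


def random_instance(rng, n_sites=None):
    """A random one-chromosome call vector with het/missing clusters."""
    n = n_sites or int(rng.integers(5, 500))
    calls = rng.choice(
        [HOM_REF, HOM_ALT, HET, MISSING], size=n, p=[0.55, 0.3, 0.1, 0.05]
    ).astype(np.int8)
    # occasionally plant a clean homozygous stretch so segments exist
    if n > 50 and rng.random() < 0.7:
        a = int(rng.integers(0, n - 40))
        calls[a : a + 40] = HOM_REF
    gaps = rng.integers(1_000, 30_000, size=n)
    if rng.random() < 0.3:  # sprinkle a big gap to exercise the split rule
        gaps[rng.integers(0, n)] = int(rng.integers(1_000_000, 3_000_000))
    positions = np.cumsum(gaps)
    return calls, positions


class TestWindowFlags:
    def test_all_hom_single_window(self):
        params = ROHParams()
        flags = window_flags(np.zeros(50, dtype=np.int8), params)
        assert flags.tolist() == [True]

    def test_het_tolerance_boundary(self):
        calls = np.zeros(50, dtype=np.int8)
        calls[[10, 30]] = HET
        assert window_flags(calls, ROHParams(window_het=1)).tolist() == [False]
        assert window_flags(calls, ROHParams(window_het=2)).tolist() == [True]

    def test_two_spread_hets_leave_all_windows_tolerant(self):
        # 60 sites, hets at 5 and 55: no 50-site window holds both
        calls = np.zeros(60, dtype=np.int8)
        calls[[5, 55]] = HET
        flags = window_flags(calls, ROHParams(window_het=1))
        assert len(flags) == 11
        assert flags.all()

    def test_missing_tolerance(self):
        calls = np.zeros(50, dtype=np.int8)
        calls[:6] = MISSING
        assert window_flags(calls, ROHParams(window_missing=5)).tolist() == [False]
        assert window_flags(calls, ROHParams(window_missing=6)).tolist() == [True]

    def test_short_chromosome_has_no_windows(self):
        assert len(window_flags(np.zeros(49, dtype=np.int8), ROHParams())) == 0


class TestSnpState:
    def test_all_windows_homozygous_covers_every_site(self):
        flags = np.ones(11, dtype=bool)
        state = snp_homozygosity_state(flags, 60, ROHParams())
        assert state.all()

    def test_no_window_homozygous_no_site_in_state(self):
        flags = np.zeros(11, dtype=bool)
        state = snp_homozygosity_state(flags, 60, ROHParams())
        assert not state.any()

    def test_zero_windows_means_no_state(self):
        state = snp_homozygosity_state(np.zeros(0, dtype=bool), 30, ROHParams())
        assert not state.any()

    def test_edge_sites_use_actual_covering_count(self):
        # window 0 hom, window 1 not: site 0 is covered only by window 0
        flags = np.array([True] + [False] * 10)
        state = snp_homozygosity_state(flags, 60, ROHParams())
        assert state[0]  # 1/1 covering windows
        # a middle site covered by many failing windows and one passing
        # window still reaches the 5% threshold (1/50 >= 0.05 is false; but
        # site 10 is covered by windows 0..10 -> 1/11 >= 0.05)
        assert state[10]

    @pytest.mark.parametrize("threshold,expect", [(0.05, True), (0.5, False)])
    def test_threshold_is_inclusive_fraction(self, threshold, expect):
        # exactly 1 of 20 covering windows homozygous: 0.05 boundary
        n_sites = 69  # site 49 covered by windows 0..19 (20 windows)
        flags = np.zeros(20, dtype=bool)
        flags[0] = True
        params = ROHParams(window_threshold=threshold)
        state = snp_homozygosity_state(flags, n_sites, params)
        assert bool(state[49]) is expect


class TestCallSegments:
    def test_uniform_hom_chromosome_single_segment(self):
        positions = np.arange(1, 1001) * 10_000  # 10 Mb, 10 kb spacing
        m = make_matrix(np.zeros((1, 1000), dtype=np.int8), positions=positions)
        cs = call_segments(m)
        assert len(cs) == 1
        seg = cs.segments[0]
        assert (seg.n_snp, seg.n_het_observed) == (1000, 0)
        assert (seg.start_pos, seg.end_pos) == (10_000, 10_000_000)

    def test_alternating_het_hom_yields_nothing(self):
        calls = np.tile([HOM_REF, HET], 500).reshape(1, -1)
        m = make_matrix(calls, positions=np.arange(1, 1001) * 1_000)
        for h in range(1, 6):
            assert len(call_segments(m, ROHParams(window_het=h))) == 0

    def test_gap_rule_splits_into_two_segments(self):
        # two 5 Mb homozygous blocks with a 1.2 Mb site gap between them
        pos_left = np.arange(1, 501) * 10_000
        pos_right = pos_left[-1] + 1_200_000 + np.arange(0, 500) * 10_000
        positions = np.concatenate([pos_left, pos_right])
        m = make_matrix(np.zeros((1, 1000), dtype=np.int8), positions=positions)
        cs = call_segments(m)
        assert len(cs) == 2
        assert cs.segments[0].end_pos == 5_000_000
        assert cs.segments[1].start_pos == 6_200_000

    def test_short_snp_count_rejected_despite_length(self):
        # 40 sites spanning 2 Mb: passes kb filter, fails the 50-SNP filter
        positions = np.arange(1, 41) * 50_000
        m = make_matrix(np.zeros((1, 40), dtype=np.int8), positions=positions)
        assert len(call_segments(m)) == 0

    def test_boundary_trimming_excludes_edge_hets(self):
        calls = np.zeros((1, 200), dtype=np.int8)
        calls[0, 60] = HET  # interior het, tolerated
        positions = np.arange(1, 201) * 10_000
        m = make_matrix(calls, positions=positions)
        seg = call_segments(m, ROHParams(window_het=1)).segments[0]
        assert seg.n_het_observed == 1
        # now make the first in-state site a het: segment must start after it
        calls2 = np.zeros((1, 200), dtype=np.int8)
        calls2[0, 0] = HET
        m2 = make_matrix(calls2, positions=positions)
        seg2 = call_segments(m2, ROHParams(window_het=1)).segments[0]
        assert seg2.start_pos == positions[1]
        assert seg2.n_het_observed == 0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            calls, positions = random_instance(rng)
            m = make_matrix(calls.reshape(1, -1), positions=positions)
            got = [
                (s.start_pos, s.end_pos, s.n_snp, s.n_het_observed)
                for s in call_segments(m, SMALL).segments
            ]
            expected = brute_force_segments(list(calls), list(positions), SMALL)
            assert got == expected

    def test_total_roh_sum_non_decreasing_in_h(self, rng):
        for _ in range(20):
            calls, positions = random_instance(rng, n_sites=400)
            m = make_matrix(calls.reshape(1, -1), positions=positions)
            sums = []
            covers = []
            for h in range(1, 6):
                cs = call_segments(m, SMALL.with_het_tolerance(h))
                sums.append(sum(s.length_bp for s in cs.segments))
                covers.append(
                    {(s.start_pos, s.end_pos) for s in cs.segments}
                )
            assert sums == sorted(sums)
            # bp containment: every segment at h is inside some segment at h+1
            for h in range(4):
                for a, b in covers[h]:
                    assert any(s <= a and b <= e for s, e in covers[h + 1])

    def test_no_het_calls_anywhere_means_zero_nhet(self, rng):
        calls = rng.choice([HOM_REF, HOM_ALT, MISSING], size=(3, 300),
                           p=[0.6, 0.35, 0.05]).astype(np.int8)
        m = make_matrix(calls, positions=np.arange(1, 301) * 5_000)
        cs = call_segments(m, SMALL)
        assert all(s.n_het_observed == 0 for s in cs.segments)

    def test_deterministic_hom_output(self, tmp_path, rng):
        calls, positions = random_instance(rng, n_sites=450)
        m = make_matrix(calls.reshape(1, -1), positions=positions)
        paths = []
        for tag in ("a", "b"):
            cs = call_segments(m, SMALL)
            p = tmp_path / f"{tag}.hom"
            write_hom_table(cs, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestParams:
    def test_plink_dict_round_trip(self):
        p = ROHParams(window_het=3)
        assert ROHParams.from_plink_dict(p.to_plink_dict()) == p

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            ROHParams.from_plink_dict({"homozyg_windw_het": 1})

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ROHParams(window_threshold=0.0)
        with pytest.raises(ValueError):
            ROHParams(min_snp_final=0)
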