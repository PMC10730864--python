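import numpy as np
import pytest

from bapfish.fish_sim import (
    PatternClass,
    SimParams,
    SimulatedPattern,
    classify_pattern,
    classify_result,
    pattern_to_iscn,
    simulate_signals,
)
from bapfish.iscn import CountInterval, SignalSummary, parse_nuc_ish, summarize_clone
from bapfish.locus_model import (
    DerivativeChromosome,
    GenomeConfiguration,
    GenomicInterval,
    ProbeColor,
    SegmentRef,
    build_diploid_reference,
)

from conftest import MINI_CHROM, MINI_LEN, random_mini_config

MINI_PARAMS = SimParams(d_fuse=1_500, min_visible_frac=0.25)


def seg(start, end, orient="+", chrom=MINI_CHROM):
    return SegmentRef(GenomicInterval(chrom, start, end), orient)


# --------------------------------------------------------------------------- #
# independent brute-force oracle: per-base masks + exhaustive pair search
# --------------------------------------------------------------------------- #


def oracle_simulate(config, probes, params):
    spots = []  # (derivative index, start, end, color)
    for d_idx, der in enumerate(config.derivatives):
        length = len(der)
        for fp in probes:
            mask = np.zeros(length, dtype=bool)
            offset = 0
            for s in der.segments:
                seg_len = len(s)
                piece = np.zeros(seg_len, dtype=bool)
                if s.interval.chrom == fp.interval.chrom:
                    lo = max(s.interval.start, fp.interval.start)
                    hi = min(s.interval.end, fp.interval.end)
                    if lo < hi:
                        piece[lo - s.interval.start : hi - s.interval.start] = True
                if s.orientation == "-":
                    piece = piece[::-1]
                mask[offset : offset + seg_len] = piece
                offset += seg_len
            padded = np.concatenate(([False], mask, [False])).astype(int)
            edges = np.flatnonzero(np.diff(padded))
            for run_start, run_end in zip(edges[::2], edges[1::2]):
                if (run_end - run_start) / len(fp.interval) >= params.min_visible_frac:
                    spots.append((d_idx, int(run_start), int(run_end), fp.color))
    reds = [s for s in spots if s[3] is ProbeColor.RED]
    greens = [s for s in spots if s[3] is ProbeColor.GREEN]
    fusions = 0
    while True:
        candidates = []
        for i, r in enumerate(reds):
            for j, g in enumerate(greens):
                if r[0] != g[0]:
                    continue
                gap = max(0, max(r[1], g[1]) - min(r[2], g[2]))
                if gap <= params.d_fuse:
                    candidates.append((gap, r[1], g[1], i, j))
        if not candidates:
            break
        candidates.sort()
        _, _, _, i, j = candidates[0]
        reds.pop(i)
        greens.pop(j)
        fusions += 1
    return len(reds), len(greens), fusions


# --------------------------------------------------------------------------- #
# simulate_signals
# --------------------------------------------------------------------------- #


class TestSimulateSignals:
    def test_diploid_reference_gives_two_fusions(self, probes):
        config = build_diploid_reference(probes)
        pattern = simulate_signals(config, probes)
        assert (pattern.n_red_isolated, pattern.n_green_isolated, pattern.n_fusion) == (0, 0, 2)

    def test_reciprocal_translocation_gives_1r1g1f(self, mini_probes):
        # breakpoint in the gap between footprints; other homolog intact
        bp = 5_500
        der_a = DerivativeChromosome("der_a", [seg(0, bp), seg(5_000, 9_000, chrom="p")])
        der_b = DerivativeChromosome("der_b", [seg(0, 5_000, chrom="p"), seg(bp, MINI_LEN)])
        intact = DerivativeChromosome("hom", [seg(0, MINI_LEN)])
        pattern = simulate_signals(
            GenomeConfiguration([intact, der_a, der_b]), mini_probes, MINI_PARAMS
        )
        assert (pattern.n_red_isolated, pattern.n_green_isolated, pattern.n_fusion) == (1, 1, 1)

    def test_extra_distant_red_copy_gives_rf_totals(self, mini_probes):
        # extra 5' footprint copy far from any green, plus an intact locus:
        # totals R=2, G=1, F=1 -> the classic unbalanced red-fusion picture
        red = mini_probes[0].interval
        amplicon = DerivativeChromosome("amp", [seg(red.start, red.end)])
        rearranged = DerivativeChromosome("der", [seg(0, MINI_LEN)])
        pattern = simulate_signals(
            GenomeConfiguration([rearranged, amplicon]), mini_probes, MINI_PARAMS
        )
        assert (pattern.n_red_isolated, pattern.n_green_isolated, pattern.n_fusion) == (1, 0, 1)
        assert oracle_simulate(
            GenomeConfiguration([rearranged, amplicon]), mini_probes, MINI_PARAMS
        ) == (1, 0, 1)

    def test_sub_threshold_remnant_is_invisible(self, mini_probes):
        red = mini_probes[0].interval
        remnant_len = int(len(red) * 0.1)  # below min_visible_frac
        remnant = DerivativeChromosome("rem", [seg(red.start, red.start + remnant_len)])
        pattern = simulate_signals(GenomeConfiguration([remnant]), mini_probes, MINI_PARAMS)
        assert (pattern.n_red_isolated, pattern.n_green_isolated, pattern.n_fusion) == (0, 0, 0)

    def test_matches_oracle_on_random_configurations(self, mini_probes):
        rng = np.random.default_rng(77)
        for _ in range(250):
            config = random_mini_config(rng)
            pattern = simulate_signals(config, mini_probes, MINI_PARAMS)
            assert (
                pattern.n_red_isolated,
                pattern.n_green_isolated,
                pattern.n_fusion,
            ) == oracle_simulate(config, mini_probes, MINI_PARAMS)

    def test_adding_distant_red_copy_is_monotone(self, mini_probes):
        # extra disjoint 5' footprint copy never decreases r_isolated + fusion
        rng = np.random.default_rng(123)
        red = mini_probes[0].interval
        for _ in range(50):
            config = random_mini_config(rng)
            base = simulate_signals(config, mini_probes, MINI_PARAMS)
            extra = DerivativeChromosome("extra_red", [seg(red.start, red.end)])
            augmented = GenomeConfiguration(list(config.derivatives) + [extra])
            more = simulate_signals(augmented, mini_probes, MINI_PARAMS)
            assert (
                more.n_red_isolated + more.n_fusion
                >= base.n_red_isolated + base.n_fusion
            )


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #


def summary(r, g, f, r_iso, g_iso):
    return SignalSummary(
        CountInterval(*r), CountInterval(*g), CountInterval(*f),
        CountInterval(*r_iso), CountInterval(*g_iso),
    )


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            (SimulatedPattern(0, 0, 2), PatternClass.NORMAL),
            (SimulatedPattern(0, 0, 3), PatternClass.FUSION_CN),
            (SimulatedPattern(1, 0, 1), PatternClass.RF),
            (SimulatedPattern(0, 1, 1), PatternClass.GF),
            (SimulatedPattern(1, 1, 1), PatternClass.RGF),
            (SimulatedPattern(2, 1, 0), PatternClass.RGF),
        ],
    )
    def test_point_patterns(self, pattern, expected):
        assert classify_pattern(pattern) is expected

    def test_gf_summary(self):
        # R=1, G=2, F=1 -> isolated green only
        s = summary((1, 1), (2, 2), (1, 1), (0, 0), (1, 1))
        assert classify_pattern(s) is PatternClass.GF

    def test_range_consistent_at_both_endpoints(self):
        s = summary((2, 4), (2, 4), (1, 2), (1, 2), (1, 2))
        assert classify_pattern(s) is PatternClass.RGF

    def test_disagreeing_endpoints_are_ambiguous(self):
        # lo endpoint: no isolated signals at ploidy -> NORMAL; hi: extra fusion
        s = summary((2, 3), (2, 3), (2, 3), (0, 0), (0, 0))
        assert classify_pattern(s) is PatternClass.AMBIGUOUS

    def test_dominant_abnormal_clone_decides_result(self):
        res = parse_nuc_ish(
            "nuc ish(5'MYCx3,3'MYCx2)(5'MYC con 3'MYCx2)[42/100]/(MYCx3)[30/100]"
        )
        assert classify_result(res) is PatternClass.RF

    def test_all_normal_clones_classify_normal(self):
        assert classify_result(parse_nuc_ish("nuc ish(MYCx2)[100]")) is PatternClass.NORMAL


class TestPatternToIscn:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            (SimulatedPattern(1, 1, 1), "nuc ish(MYCx2)(5'MYC sep 3'MYCx1)[100]"),
            (SimulatedPattern(0, 0, 2), "nuc ish(MYCx2)[100]"),
            (SimulatedPattern(1, 0, 1), "nuc ish(5'MYCx2,3'MYCx1)(5'MYC con 3'MYCx1)[100]"),
        ],
    )
    def test_emitted_forms(self, pattern, expected):
        from bapfish.iscn import format_nuc_ish

        assert format_nuc_ish(pattern_to_iscn(pattern)) == expected

    def test_closure_under_summarize_and_classify(self):
        # classify(summarize(pattern_to_iscn(p))) == classify(p) for all
        # plausible small patterns
        for r in range(4):
            for g in range(4):
                for f in range(4):
                    if r + g + f == 0:
                        continue
                    p = SimulatedPattern(r, g, f)
                    back = summarize_clone(pattern_to_iscn(p).clones[0])
                    assert classify_pattern(back) is classify_pattern(p), (r, g, f)
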