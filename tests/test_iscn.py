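import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bapfish.iscn import (
    CountInterval,
    IscnSemanticError,
    IscnSyntaxError,
    NucIshClone,
    ProbeCount,
    ProbeTarget,
    RelationKind,
    RelationTerm,
    format_nuc_ish,
    parse_nuc_ish,
    summarize_clone,
)


def ci(lo, hi=None):
    return CountInterval(lo, lo if hi is None else hi)


class TestParse:
    def test_single_clone_with_con_term(self):
        res = parse_nuc_ish("nuc ish(5′MYCx2,3′MYCx1)(5′MYC con 3′MYCx1)[100]")
        (clone,) = res.clones
        assert clone.probe_counts == (
            ProbeCount(ProbeTarget.FIVE_PRIME, ci(2)),
            ProbeCount(ProbeTarget.THREE_PRIME, ci(1)),
        )
        assert clone.relations == (RelationTerm(RelationKind.CON, ci(1)),)
        assert (clone.cells_observed, clone.cells_total) == (100, 100)

    def test_bare_myc_token_sets_both_probes(self):
        res = parse_nuc_ish("nuc ish(MYCx2)[100]")
        (clone,) = res.clones
        assert clone.probe_counts == (ProbeCount(ProbeTarget.BOTH, ci(2)),)
        assert clone.relations == ()

    def test_ranges_tilde_hyphen_and_spaces(self):
        res = parse_nuc_ish("nuc ish(5′MYCx2~3,3′MYCx1-2)(5′MYC con 3′MYCx1-2)[97/100]")
        (clone,) = res.clones
        assert clone.probe_counts[0].count == ci(2, 3)
        assert clone.probe_counts[1].count == ci(1, 2)
        assert clone.relations[0].count == ci(1, 2)
        assert (clone.cells_observed, clone.cells_total) == (97, 100)

    def test_stray_comma_after_prefix_tolerated(self):
        res = parse_nuc_ish("nuc ish,(5′MYCx2 ~ 3,3′MYCx1-2)(5′MYC con 3′MYCx1-2)[97/100]")
        assert res.clones[0].probe_counts[0].count == ci(2, 3)

    def test_shared_multiplier_expands_to_both_probes(self):
        res = parse_nuc_ish("nuc ish(5′MYC,3′MYC)x2∼4(5′MYC con 3′MYCx1 ~ 2)[93/100]")
        (clone,) = res.clones
        assert clone.probe_counts == (
            ProbeCount(ProbeTarget.FIVE_PRIME, ci(2, 4)),
            ProbeCount(ProbeTarget.THREE_PRIME, ci(2, 4)),
        )

    def test_multiple_clones(self):
        res = parse_nuc_ish(
            "nuc ish(5’MYCx3,3′MYCx2)(5’MYC con 3′MYCx2)[42/100]/(MYCx3)[30/100]"
        )
        assert len(res.clones) == 2
        assert res.clones[1].probe_counts == (ProbeCount(ProbeTarget.BOTH, ci(3)),)
        assert res.clones[1].cells_observed == 30

    def test_syntax_error_carries_offset(self):
        with pytest.raises(IscnSyntaxError) as exc:
            parse_nuc_ish("nuc ish(5'MYCx2,3'MYCx1)(5'MYC smush 3'MYCx1)[100]")
        assert exc.value.offset > 0

    def test_empty_input_rejected(self):
        with pytest.raises(IscnSyntaxError):
            parse_nuc_ish("   ")

    def test_cells_observed_above_total_rejected(self):
        with pytest.raises(IscnSemanticError):
            parse_nuc_ish("nuc ish(MYCx2)[101/100]")

    def test_clone_fractions_exceeding_total_rejected(self):
        with pytest.raises(IscnSemanticError):
            parse_nuc_ish("nuc ish(MYCx2)[60/100]/(MYCx3)[50/100]")

    def test_mixed_con_and_sep_rejected(self):
        with pytest.raises(IscnSemanticError):
            parse_nuc_ish(
                "nuc ish(5'MYCx2,3'MYCx2)(5'MYC con 3'MYCx1)(5'MYC sep 3'MYCx1)[100]"
            )


# Expected summaries derived by evaluating the fusion rule by hand at both
# range endpoints: F = con, or min(R,G) - sep, or min(R,G).
SUMMARY_CASES = [
    # (string, r_total, g_total, fusion, r_isolated, g_isolated)
    ("nuc ish(5′MYCx2,3′MYCx1)(5′MYC con 3′MYCx1)[100]", ci(2), ci(1), ci(1), ci(1), ci(0)),
    ("nuc ish(MYCx2)(5′MYC sep 3′MYCx1)[96/100]", ci(2), ci(2), ci(1), ci(1), ci(1)),
    ("nuc ish(MYCx3)[100]", ci(3), ci(3), ci(3), ci(0), ci(0)),
    ("nuc ish(5’MYCx1,3’MYCx2)(5’MYC con 3’MYCx1)[68/100]", ci(1), ci(2), ci(1), ci(0), ci(1)),
    (
        "nuc ish(5’MYCx2 ~ 5,3’MYCx1 ~ 2)(5’MYC con 3’MYCx1∼2)[100]",
        ci(2, 5), ci(1, 2), ci(1, 2), ci(1, 3), ci(0, 0),
    ),
    (
        "nuc ish(5′MYCx2 ~ 4,3′MYCx2 ~ 4)(5′MYC sep 3′MYCx1)[90/100]",
        ci(2, 4), ci(2, 4), ci(1, 3), ci(1, 1), ci(1, 1),
    ),
]


class TestSummarize:
    @pytest.mark.parametrize("text,r,g,f,r_iso,g_iso", SUMMARY_CASES)
    def test_fusion_rule(self, text, r, g, f, r_iso, g_iso):
        summary = summarize_clone(parse_nuc_ish(text).clones[0])
        assert summary.r_total == r
        assert summary.g_total == g
        assert summary.fusion == f
        assert summary.r_isolated == r_iso
        assert summary.g_isolated == g_iso

    def test_negative_isolated_count_rejected(self):
        # con term larger than either probe total is impossible
        with pytest.raises(IscnSemanticError):
            summarize_clone(parse_nuc_ish("nuc ish(5'MYCx1,3'MYCx1)(5'MYC con 3'MYCx3)[100]").clones[0])

    def test_conservation_for_every_accepted_clone(self, cases):
        # isolated + fusion recovers the probe totals at both endpoints
        for record in cases:
            for clone in parse_nuc_ish(record.nuc_ish).clones:
                s = summarize_clone(clone)
                assert (s.r_isolated.lo + s.fusion.lo, s.r_isolated.hi + s.fusion.hi) == (
                    s.r_total.lo, s.r_total.hi
                )
                assert (s.g_isolated.lo + s.fusion.lo, s.g_isolated.hi + s.fusion.hi) == (
                    s.g_total.lo, s.g_total.hi
                )


PRIMES = ["′", "’", "'"]
TILDES = ["∼", "~"]


def fuzz_dialect(text: str, rng: random.Random) -> str:
    """Randomise typographic variants and interior whitespace."""
    out = []
    for ch in text:
        if ch in PRIMES:
            ch = rng.choice(PRIMES)
        elif ch in TILDES:
            ch = rng.choice(TILDES + ["-"])
        out.append(ch)
        if rng.random() < 0.08:
            out.append(" " * rng.randint(1, 2))
    return "".join(out)


class TestRoundTripAndDialect:
    def test_round_trip_all_cohort_strings(self, cases):
        for record in cases:
            first = parse_nuc_ish(record.nuc_ish)
            emitted = format_nuc_ish(first)
            assert parse_nuc_ish(emitted) == first

    def test_canonical_form_of_simple_case(self):
        res = parse_nuc_ish("nuc ish(5’MYCx1,3’MYCx2)(5’MYC con 3’MYCx1)[68/100]")
        assert format_nuc_ish(res) == "nuc ish(5'MYCx1,3'MYCx2)(5'MYC con 3'MYCx1)[68/100]"

    @staticmethod
    @st.composite
    def nuc_ish_results(draw):
        from bapfish.iscn import NucIshClone, NucIshResult

        def interval():
            lo = draw(st.integers(0, 6))
            return CountInterval(lo, lo + draw(st.integers(0, 3)))

        clones = []
        budget = 100
        for _ in range(draw(st.integers(1, 2))):
            if draw(st.booleans()):
                probes = (ProbeCount(ProbeTarget.BOTH, interval()),)
            else:
                probes = (
                    ProbeCount(ProbeTarget.FIVE_PRIME, interval()),
                    ProbeCount(ProbeTarget.THREE_PRIME, interval()),
                )
            relations = ()
            if draw(st.booleans()):
                kind = draw(st.sampled_from([RelationKind.CON, RelationKind.SEP]))
                relations = (RelationTerm(kind, interval()),)
            observed = draw(st.integers(1, max(1, budget // 2)))
            budget -= observed
            clones.append(NucIshClone(probes, relations, observed, 100))
        return NucIshResult(tuple(clones))

    @given(result=nuc_ish_results())
    @settings(max_examples=200, derandomize=True)
    def test_arbitrary_results_round_trip(self, result):
        assert parse_nuc_ish(format_nuc_ish(result)) == result

    def test_dialect_fuzzing_leaves_parse_unchanged(self, cases):
        rng = random.Random(2024)
        for record in cases:
            reference = parse_nuc_ish(record.nuc_ish)
            for _ in range(75):  # 14 * 75 > 1000 fuzzed variants
                variant = fuzz_dialect(record.nuc_ish, rng)
                assert parse_nuc_ish(variant) == reference
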