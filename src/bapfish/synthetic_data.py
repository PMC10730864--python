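"""Seeded synthetic rearrangement scenarios with known ground-truth pattern class.

Each archetype emulates a rearrangement family seen at the *MYC* locus in
DLBCL/HGBCL — balanced translocation, unbalanced juxtaposition with relative
5' gain or 3' loss, whole-locus copy gain, focal deletion removing *MYC* and
the 5' probe, templated insertion, and genic intron-1 breakpoints — built on
the modelled chr8 locus plus an abstract labelled partner chromosome (pattern
class depends only on topology, so no real partner coordinates are needed).

The ground-truth class of a scenario is fixed analytically by its archetype,
never by running the simulator, which is what makes the end-to-end recovery
property (classify(simulate(scenario)) == truth) a real test.

Breakpoints are drawn uniformly within archetype-legal windows; a fixed seed
makes every scenario byte-reproducible, including its VCF/SEG export.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fish_sim import PatternClass
from .locus_model import (
    Breakend,
    CNSegment,
    DerivativeChromosome,
    GenomeConfiguration,
    GenomicInterval,
    Junction,
    LocusModelError,
    SegmentRef,
    Side,
    DEFAULT_GREEN_INTERVAL,
    DEFAULT_RED_INTERVAL,
    MYC_GENE,
)


class SyntheticError(ValueError):
    pass


#: Modelled chromosome lengths (GRCh38-like chr8; abstract partner).
CONTIG_LENGTHS: dict[str, int] = {
    "chr8": 145_138_636,
    "partner_1": 100_000_000,
}

# Archetype-legal breakpoint windows (half-open), all on the modelled locus.
WINDOW_GAP_3P = (127_743_500, 127_930_000)  # telomeric of MYC, centromeric of green
WINDOW_INTRON1 = (127_736_000, 127_737_500)  # within MYC intron 1
WINDOW_5P_FLANK = (127_100_000, 127_330_000)  # centromeric of the red footprint
WINDOW_INSERTION_SITE = (20_000_000, 30_000_000)  # distant chr8p insertion site
WINDOW_PARTNER = (40_000_000, 60_000_000)  # abstract partner breakpoint


class Archetype(enum.Enum):
    NORMAL = "NORMAL"
    BALANCED_TRANSLOCATION = "BALANCED_TRANSLOCATION"
    UNBALANCED_5P_GAIN = "UNBALANCED_5P_GAIN"
    UNBALANCED_3P_LOSS = "UNBALANCED_3P_LOSS"
    WHOLE_LOCUS_GAIN = "WHOLE_LOCUS_GAIN"
    DELETION_5P_AND_MYC = "DELETION_5P_AND_MYC"
    TEMPLATED_INSERTION = "TEMPLATED_INSERTION"
    GENIC_INTRON1_BREAK = "GENIC_INTRON1_BREAK"


#: Analytic ground-truth class per archetype (intron-1 breaks depend on the
#: ``reciprocal`` parameter and are resolved in :func:`generate_scenario`).
TRUTH_BY_ARCHETYPE: dict[Archetype, PatternClass] = {
    Archetype.NORMAL: PatternClass.NORMAL,
    Archetype.BALANCED_TRANSLOCATION: PatternClass.RGF,
    Archetype.UNBALANCED_5P_GAIN: PatternClass.RF,
    Archetype.UNBALANCED_3P_LOSS: PatternClass.RF,
    Archetype.WHOLE_LOCUS_GAIN: PatternClass.FUSION_CN,
    Archetype.DELETION_5P_AND_MYC: PatternClass.GF,
    Archetype.TEMPLATED_INSERTION: PatternClass.RF,
}


@dataclass(frozen=True)
class ScenarioSpec:
    archetype: Archetype
    seed: int
    params: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class Scenario:
    spec: ScenarioSpec
    config: GenomeConfiguration
    truth_class: PatternClass
    description: str
    junctions: tuple[Junction, ...] = ()
    cn_segments: tuple[CNSegment, ...] = ()


# --------------------------------------------------------------------------- #
# helpers
# --------------------------------------------------------------------------- #


def _chrom_segment(chrom: str, start: int | None = None, end: int | None = None) -> SegmentRef:
    length = CONTIG_LENGTHS[chrom]
    return SegmentRef(GenomicInterval(chrom, start or 0, end if end is not None else length))


def _homolog(name: str, chrom: str) -> DerivativeChromosome:
    return DerivativeChromosome(name, [_chrom_segment(chrom)])


def _draw(rng: np.random.Generator, window: tuple[int, int], name: str) -> int:
    lo, hi = int(window[0]), int(window[1])
    default_lo, default_hi = _DEFAULT_WINDOWS[name]
    if not (default_lo <= lo < hi <= default_hi):
        raise SyntheticError(
            f"{name} window [{lo},{hi}) falls outside the modelled locus "
            f"[{default_lo},{default_hi})"
        )
    return int(rng.integers(lo, hi))


_DEFAULT_WINDOWS = {
    "break_window": WINDOW_GAP_3P,
    "intron1_window": WINDOW_INTRON1,
    "flank_window": WINDOW_5P_FLANK,
    "insertion_window": WINDOW_INSERTION_SITE,
    "partner_window": WINDOW_PARTNER,
}


def _window(params: Mapping[str, object], name: str) -> tuple[int, int]:
    return tuple(params.get(name, _DEFAULT_WINDOWS[name]))  # type: ignore[return-value]


# --------------------------------------------------------------------------- #
# archetype builders
# --------------------------------------------------------------------------- #


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Build one scenario; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    arch = spec.archetype
    p = spec.params
    partner = "partner_1"
    derivatives: list[DerivativeChromosome]
    junctions: list[Junction] = []
    cn_segments: list[CNSegment] = []

    if arch is Archetype.NORMAL:
        derivatives = [_homolog("chr8_a", "chr8"), _homolog("chr8_b", "chr8")]
        truth = PatternClass.NORMAL
        desc = "diploid reference, intact MYC locus on both homologs"

    elif arch in (Archetype.BALANCED_TRANSLOCATION, Archetype.GENIC_INTRON1_BREAK):
        window = (
            _window(p, "intron1_window")
            if arch is Archetype.GENIC_INTRON1_BREAK
            else _window(p, "break_window")
        )
        wname = "intron1_window" if arch is Archetype.GENIC_INTRON1_BREAK else "break_window"
        bp = _draw(rng, window, wname)
        pp = _draw(rng, _window(p, "partner_window"), "partner_window")
        reciprocal = bool(p.get("reciprocal", True))
        j_a = Junction(
            Breakend("chr8", bp, Side.LEFT), Breakend(partner, pp, Side.RIGHT),
            partner_label=partner, event_id="der_a",
        )
        j_b = Junction(
            Breakend(partner, pp, Side.LEFT), Breakend("chr8", bp, Side.RIGHT),
            partner_label=partner, event_id="der_b",
        )
        der_b = DerivativeChromosome(
            "der_b", [_chrom_segment(partner, 0, pp), _chrom_segment("chr8", bp)]
        )
        derivatives = [_homolog("chr8_a", "chr8"), _homolog("partner_a", partner), der_b]
        junctions.append(j_b)
        if reciprocal:
            der_a = DerivativeChromosome(
                "der_a", [_chrom_segment("chr8", 0, bp), _chrom_segment(partner, pp)]
            )
            derivatives.append(der_a)
            junctions.append(j_a)
            truth = PatternClass.RGF
        else:
            truth = PatternClass.GF
        site = "MYC intron 1" if arch is Archetype.GENIC_INTRON1_BREAK else "telomeric of MYC"
        desc = (
            f"{'reciprocal' if reciprocal else 'one-sided'} translocation at "
            f"chr8:{bp} ({site}) with {partner}:{pp}"
        )

    elif arch is Archetype.UNBALANCED_3P_LOSS:
        bp = _draw(rng, _window(p, "break_window"), "break_window")
        pp = _draw(rng, _window(p, "partner_window"), "partner_window")
        junctions.append(
            Junction(
                Breakend("chr8", bp, Side.LEFT), Breakend(partner, pp, Side.RIGHT),
                partner_label=partner, event_id="der_a",
            )
        )
        der_a = DerivativeChromosome(
            "der_a", [_chrom_segment("chr8", 0, bp), _chrom_segment(partner, pp)]
        )
        derivatives = [_homolog("chr8_a", "chr8"), _homolog("partner_a", partner), der_a]
        truth = PatternClass.RF
        desc = (
            f"unbalanced juxtaposition at chr8:{bp}: the derivative retains 5' "
            f"material; sequence 3' of the breakpoint (green footprint) is lost"
        )

    elif arch is Archetype.UNBALANCED_5P_GAIN:
        gain_start = _draw(rng, _window(p, "flank_window"), "flank_window")
        bp = _draw(rng, _window(p, "break_window"), "break_window")
        pp = _draw(rng, _window(p, "partner_window"), "partner_window")
        junctions.append(
            Junction(
                Breakend("chr8", bp, Side.LEFT), Breakend(partner, pp, Side.RIGHT),
                partner_label=partner, event_id="gain_der",
            )
        )
        cn_segments.append(CNSegment(GenomicInterval("chr8", gain_start, bp), 3))
        gain_der = DerivativeChromosome(
            "gain_der", [_chrom_segment("chr8", gain_start, bp), _chrom_segment(partner, pp)]
        )
        derivatives = [
            _homolog("chr8_a", "chr8"), _homolog("chr8_b", "chr8"),
            _homolog("partner_a", partner), gain_der,
        ]
        truth = PatternClass.RF
        desc = (
            f"extra copy of chr8:{gain_start}-{bp} (5' of MYC, spanning the red "
            f"footprint) juxtaposed to {partner}:{pp}"
        )

    elif arch is Archetype.WHOLE_LOCUS_GAIN:
        derivatives = [_homolog(f"chr8_{s}", "chr8") for s in "abc"]
        cn_segments.append(CNSegment(GenomicInterval("chr8", 0, CONTIG_LENGTHS["chr8"]), 3))
        truth = PatternClass.FUSION_CN
        desc = "whole-chromosome gain: three intact copies of the MYC locus"

    elif arch is Archetype.DELETION_5P_AND_MYC:
        a = _draw(rng, _window(p, "flank_window"), "flank_window")
        b = _draw(rng, _window(p, "break_window"), "break_window")
        cn_segments.append(CNSegment(GenomicInterval("chr8", a, b), 1))
        del_der = DerivativeChromosome(
            "del_der", [_chrom_segment("chr8", 0, a), _chrom_segment("chr8", b)]
        )
        derivatives = [_homolog("chr8_a", "chr8"), del_der]
        truth = PatternClass.GF
        desc = f"focal deletion chr8:{a}-{b} removing the red footprint and MYC on one homolog"

    elif arch is Archetype.TEMPLATED_INSERTION:
        site = _draw(rng, _window(p, "insertion_window"), "insertion_window")
        a = _draw(rng, _window(p, "flank_window"), "flank_window")
        b = _draw(rng, _window(p, "break_window"), "break_window")
        junctions.append(
            Junction(
                Breakend("chr8", site, Side.LEFT), Breakend("chr8", a, Side.RIGHT),
                event_id="ins_left",
            )
        )
        junctions.append(
            Junction(
                Breakend("chr8", b, Side.LEFT), Breakend("chr8", site, Side.RIGHT),
                event_id="ins_right",
            )
        )
        cn_segments.append(CNSegment(GenomicInterval("chr8", a, b), 3))
        ins_der = DerivativeChromosome(
            "ins_der",
            [
                _chrom_segment("chr8", 0, site),
                _chrom_segment("chr8", a, b),
                _chrom_segment("chr8", site),
            ],
        )
        derivatives = [_homolog("chr8_a", "chr8"), ins_der]
        truth = PatternClass.RF
        desc = (
            f"templated insertion of chr8:{a}-{b} (red footprint and MYC) at "
            f"chr8:{site}; source locus intact"
        )

    else:  # pragma: no cover - exhaustiveness guard
        raise SyntheticError(f"unknown archetype {arch!r}")

    config = GenomeConfiguration(derivatives, label=arch.value.lower())
    return Scenario(
        spec=spec,
        config=config,
        truth_class=truth,
        description=desc,
        junctions=tuple(junctions),
        cn_segments=tuple(cn_segments),
    )


# --------------------------------------------------------------------------- #
# cohorts
# --------------------------------------------------------------------------- #

#: Mix mirroring a 14-case validation cohort: 7 scenarios producing the
#: balanced RGF pattern, 5 producing RF and 2 producing GF.
COHORT_14_MIX: dict[Archetype, float] = {
    Archetype.BALANCED_TRANSLOCATION: 7 / 14,
    Archetype.UNBALANCED_3P_LOSS: 2 / 14,
    Archetype.UNBALANCED_5P_GAIN: 2 / 14,
    Archetype.TEMPLATED_INSERTION: 1 / 14,
    Archetype.DELETION_5P_AND_MYC: 2 / 14,
}


def _apportion(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n among weights (deterministic)."""
    quotas = [n * w for w in weights]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    n: int,
    mix: Mapping[Archetype, float] | None = None,
    seed: int = 0,
) -> list[Scenario]:
    """A reproducible cohort of n scenarios with archetype frequencies matching
    the mix (exactly, whenever n times a weight is integral)."""
    if n <= 0:
        raise SyntheticError("cohort size must be > 0")
    if mix is None:
        mix = {a: 1 / len(Archetype) for a in Archetype}
    archetypes = list(mix.keys())
    weights = [float(mix[a]) for a in archetypes]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise SyntheticError(f"mix weights must sum to 1, got {sum(weights)}")
    counts = _apportion(n, weights)
    assigned = [a for a, c in zip(archetypes, counts) for _ in range(c)]
    rng = np.random.default_rng(seed)
    rng.shuffle(assigned)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    return [
        generate_scenario(ScenarioSpec(arch, int(child_seeds[i])))
        for i, arch in enumerate(assigned)
    ]


# --------------------------------------------------------------------------- #
# serialisation
# --------------------------------------------------------------------------- #


def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "archetype": scenario.spec.archetype.value,
        "seed": scenario.spec.seed,
        "params": dict(scenario.spec.params),
        "truth_class": scenario.truth_class.value,
        "description": scenario.description,
        "derivatives": [
            {
                "name": der.name,
                "segments": [
                    [s.interval.chrom, s.interval.start, s.interval.end, s.orientation]
                    for s in der.segments
                ],
            }
            for der in scenario.config.derivatives
        ],
        "junctions": [
            {
                "a": [j.breakend_a.chrom, j.breakend_a.pos, j.breakend_a.side.value],
                "b": [j.breakend_b.chrom, j.breakend_b.pos, j.breakend_b.side.value],
                "event_id": j.event_id,
                "partner_label": j.partner_label,
            }
            for j in scenario.junctions
        ],
        "cn_segments": [
            [c.interval.chrom, c.interval.start, c.interval.end, c.copy_number]
            for c in scenario.cn_segments
        ],
    }


def scenario_to_json(scenario: Scenario) -> str:
    """Canonical (sorted-key) JSON; byte-identical for identical specs."""
    return json.dumps(scenario_to_dict(scenario), sort_keys=True, indent=2)
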