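"""In-silico hybridisation of the break-apart probe pair.

Given a rearranged genome (a :class:`~bapfish.locus_model.GenomeConfiguration`)
the simulator maps each probe footprint onto every derivative chromosome,
emits one signal spot per maximal contiguous run of footprint bases that is
large enough to be visible, merges colocalised red/green spots into fusion
signals, and classifies the resulting pattern into the break-apart categories:

NORMAL     no isolated signals, fusion count equals ploidy
RGF        isolated red AND isolated green (balanced separation — the typical
           rearrangement pattern)
RF         isolated red without isolated green
GF         isolated green without isolated red
FUSION_CN  no isolated signals but a fusion count differing from ploidy
           (pure copy-number change of the intact locus)
AMBIGUOUS  the two endpoints of a count range classify differently

Two instrument-resolution stand-ins are explicit parameters rather than
hidden constants: ``d_fuse``, the genomic gap below which a red and a green
spot on one derivative are optically inseparable and score as a fusion, and
``min_visible_frac``, the minimum fraction of a footprint that still yields a
visible spot.  Interphase colocalisation resolution is not knowable from
nomenclature alone, so both are documented assumptions (defaults 1 Mb / 0.3)
and every shipped reconstruction is insensitive to 2-fold changes in either.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .iscn import (
    CountInterval,
    NucIshClone,
    NucIshResult,
    ProbeCount,
    ProbeTarget,
    RelationKind,
    RelationTerm,
    SignalSummary,
    summarize_clone,
)
from .locus_model import (
    GenomeConfiguration,
    ProbeColor,
    ProbeFootprint,
    validate_probe_pair,
)


class PatternClass(enum.Enum):
    NORMAL = "NORMAL"
    RGF = "RGF"
    RF = "RF"
    GF = "GF"
    FUSION_CN = "FUSION_CN"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class SimParams:
    """Tunable optical-resolution model. Distances in bases."""

    d_fuse: int = 1_000_000
    min_visible_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.d_fuse <= 0:
            raise ValueError("d_fuse must be > 0")
        if not 0 < self.min_visible_frac <= 1:
            raise ValueError("min_visible_frac must be in (0, 1]")


@dataclass(frozen=True)
class SignalSpot:
    """One visible hybridisation spot on a derivative chromosome."""

    derivative: str
    start: int  # derivative coordinates, half-open
    end: int
    color: ProbeColor
    intensity_fraction: float


@dataclass(frozen=True)
class SimulatedPattern:
    n_red_isolated: int
    n_green_isolated: int
    n_fusion: int
    clone_fraction: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_red_isolated, self.n_green_isolated, self.n_fusion) < 0:
            raise ValueError("signal counts must be >= 0")


# --------------------------------------------------------------------------- #
# spot emission
# --------------------------------------------------------------------------- #


def _footprint_pieces(der, footprint: ProbeFootprint) -> list[tuple[int, int]]:
    """Project the footprint onto one derivative; returns half-open pieces in
    derivative coordinates, in derivative order."""
    pieces: list[tuple[int, int]] = []
    offset = 0
    fp = footprint.interval
    for seg in der.segments:
        ov = seg.interval.overlap(fp)
        if ov > 0:
            lo = max(seg.interval.start, fp.start)
            hi = min(seg.interval.end, fp.end)
            if seg.orientation == "+":
                start = offset + (lo - seg.interval.start)
            else:
                start = offset + (seg.interval.end - hi)
            pieces.append((start, start + ov))
        offset += len(seg)
    return sorted(pieces)


def _merge_runs(pieces: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge touching/overlapping pieces into maximal contiguous runs."""
    runs: list[list[int]] = []
    for start, end in pieces:
        if runs and start <= runs[-1][1]:
            runs[-1][1] = max(runs[-1][1], end)
        else:
            runs.append([start, end])
    return [(s, e) for s, e in runs]


def emit_spots(
    config: GenomeConfiguration,
    probes: list[ProbeFootprint],
    params: SimParams | None = None,
) -> list[SignalSpot]:
    """All visible spots of both probes across the configuration."""
    params = params or SimParams()
    validate_probe_pair(probes)
    spots: list[SignalSpot] = []
    for der in config.derivatives:
        for fp in probes:
            fp_len = len(fp.interval)
            for start, end in _merge_runs(_footprint_pieces(der, fp)):
                frac = (end - start) / fp_len
                if frac >= params.min_visible_frac:
                    spots.append(
                        SignalSpot(der.name, start, end, fp.color, min(frac, 1.0))
                    )
    return spots


# --------------------------------------------------------------------------- #
# fusion merging
# --------------------------------------------------------------------------- #


def _gap(a: SignalSpot, b: SignalSpot) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _merge_fusions(spots: list[SignalSpot], params: SimParams) -> tuple[int, int, int]:
    """Greedy nearest-pair fusion merging, per derivative, each spot used once.

    Ties on gap are broken deterministically by (red.start, green.start).
    Returns (n_red_isolated, n_green_isolated, n_fusion).
    """
    reds = sorted(
        (s for s in spots if s.color is ProbeColor.RED), key=lambda s: (s.derivative, s.start)
    )
    greens = sorted(
        (s for s in spots if s.color is ProbeColor.GREEN), key=lambda s: (s.derivative, s.start)
    )
    n_fusion = 0
    while True:
        best: tuple[int, int, int] | None = None  # (gap, red index, green index)
        for ri, r in enumerate(reds):
            for gi, g in enumerate(greens):
                if r.derivative != g.derivative:
                    continue
                gap = _gap(r, g)
                if gap > params.d_fuse:
                    continue
                key = (gap, r.start, g.start)
                if best is None or key < (best[0], reds[best[1]].start, greens[best[2]].start):
                    best = (gap, ri, gi)
        if best is None:
            break
        _, ri, gi = best
        del reds[ri]
        del greens[gi]
        n_fusion += 1
    return len(reds), len(greens), n_fusion


def simulate_signals(
    config: GenomeConfiguration,
    probes: list[ProbeFootprint],
    params: SimParams | None = None,
) -> SimulatedPattern:
    """Hybridise the probe pair onto a genome configuration in silico."""
    params = params or SimParams()
    spots = emit_spots(config, probes, params)
    n_r, n_g, n_f = _merge_fusions(spots, params)
    return SimulatedPattern(n_r, n_g, n_f, clone_fraction=config.clone_fraction)


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #


def _classify_point(r_iso: int, g_iso: int, fusion: int, ploidy: int) -> PatternClass:
    if r_iso > 0 and g_iso > 0:
        return PatternClass.RGF
    if r_iso > 0:
        return PatternClass.RF
    if g_iso > 0:
        return PatternClass.GF
    return PatternClass.NORMAL if fusion == ploidy else PatternClass.FUSION_CN


def classify_pattern(
    summary: SignalSummary | SimulatedPattern, ploidy: int = 2
) -> PatternClass:
    """Classify a signal pattern into the break-apart categories.

    A :class:`SignalSummary` carries count ranges; it is classified at both
    range endpoints and reported AMBIGUOUS when the endpoints disagree.
    """
    if isinstance(summary, SimulatedPattern):
        return _classify_point(
            summary.n_red_isolated, summary.n_green_isolated, summary.n_fusion, ploidy
        )
    lo = _classify_point(
        summary.r_isolated.lo, summary.g_isolated.lo, summary.fusion.lo, ploidy
    )
    hi = _classify_point(
        summary.r_isolated.hi, summary.g_isolated.hi, summary.fusion.hi, ploidy
    )
    return lo if lo is hi else PatternClass.AMBIGUOUS


def classify_result(result: NucIshResult, ploidy: int = 2) -> PatternClass:
    """Classify a parsed multi-clone result by its dominant abnormal clone.

    The dominant abnormal clone is the non-NORMAL clone observed in the most
    cells (first wins ties); a result whose clones are all NORMAL is NORMAL.
    """
    best: tuple[int, PatternClass] | None = None
    for clone in result.clones:
        cls = classify_pattern(summarize_clone(clone, ploidy), ploidy)
        if cls is PatternClass.NORMAL:
            continue
        if best is None or clone.cells_observed > best[0]:
            best = (clone.cells_observed, cls)
    return best[1] if best else PatternClass.NORMAL


# --------------------------------------------------------------------------- #
# closing the loop: simulated pattern -> nomenclature
# --------------------------------------------------------------------------- #


def pattern_to_iscn(pattern: SimulatedPattern, cells_total: int = 100) -> NucIshResult:
    """Render a simulated pattern as canonical nomenclature.

    The emitted clone reproduces the pattern under :func:`summarize_clone`:
    both colors isolated -> a ``sep`` term; one color isolated next to a
    fusion -> a ``con`` term; no isolated signals -> bare counts.
    """
    r_total = pattern.n_red_isolated + pattern.n_fusion
    g_total = pattern.n_green_isolated + pattern.n_fusion
    if r_total == g_total:
        counts = (ProbeCount(ProbeTarget.BOTH, CountInterval.exact(r_total)),)
    else:
        counts = (
            ProbeCount(ProbeTarget.FIVE_PRIME, CountInterval.exact(r_total)),
            ProbeCount(ProbeTarget.THREE_PRIME, CountInterval.exact(g_total)),
        )
    relations: tuple[RelationTerm, ...] = ()
    if pattern.n_red_isolated > 0 and pattern.n_green_isolated > 0:
        sep = min(r_total, g_total) - pattern.n_fusion
        relations = (RelationTerm(RelationKind.SEP, CountInterval.exact(sep)),)
    elif (pattern.n_red_isolated > 0 or pattern.n_green_isolated > 0) and pattern.n_fusion > 0:
        relations = (RelationTerm(RelationKind.CON, CountInterval.exact(pattern.n_fusion)),)
    observed = max(1, round(pattern.clone_fraction * cells_total))
    clone = NucIshClone(counts, relations, observed, cells_total)
    return NucIshResult((clone,))
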