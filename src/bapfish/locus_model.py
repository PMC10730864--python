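"""Reference locus, probe footprints, breakpoint junctions and derivative chromosomes.

The *MYC* break-apart (BAP) assay places a red probe 5' (centromeric) and a
green probe 3' (telomeric) of the gene.  Everything downstream of this module
reasons about rearranged genomes as ordered lists of reference segments
("derivative chromosomes"), so the only genomic facts that matter are the
relative positions of probe footprints and breakpoints — not sequence.

Coordinates are 0-based, half-open throughout; conversion to the 1-based VCF
convention happens exclusively at the VCF boundary (see :mod:`bapfish.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class LocusModelError(ValueError):
    """Invalid locus-model input (bad interval, probe layout, junction, ...)."""


class AssemblyError(LocusModelError):
    """A junction is inconsistent with the segment order it is supposed to join."""


# --------------------------------------------------------------------------- #
# intervals and probes
# --------------------------------------------------------------------------- #


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise LocusModelError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise LocusModelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise LocusModelError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 for different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


class ProbeColor(enum.Enum):
    RED = "RED"
    GREEN = "GREEN"


class ProbeLabel(enum.Enum):
    FIVE_PRIME_MYC = "FIVE_PRIME_MYC"
    THREE_PRIME_MYC = "THREE_PRIME_MYC"


#: Conventional fluorophore assignment of the commercial BAP design.
PROBE_COLORS = {
    ProbeLabel.FIVE_PRIME_MYC: ProbeColor.RED,
    ProbeLabel.THREE_PRIME_MYC: ProbeColor.GREEN,
}


@dataclass(frozen=True)
class ProbeFootprint:
    """Hybridisation footprint of one BAP probe."""

    label: ProbeLabel
    color: ProbeColor
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if PROBE_COLORS[self.label] is not self.color:
            raise LocusModelError(
                f"{self.label.value} must be {PROBE_COLORS[self.label].value}"
            )


def validate_probe_pair(probes: Sequence[ProbeFootprint]) -> tuple[ProbeFootprint, ProbeFootprint]:
    """Check a 5'/3' probe pair: both present, same chromosome, red centromeric
    to green, footprints disjoint.  Returns (red, green)."""
    by_label = {p.label: p for p in probes}
    if set(by_label) != {ProbeLabel.FIVE_PRIME_MYC, ProbeLabel.THREE_PRIME_MYC} or len(probes) != 2:
        raise LocusModelError("need exactly one 5' and one 3' probe footprint")
    red = by_label[ProbeLabel.FIVE_PRIME_MYC]
    green = by_label[ProbeLabel.THREE_PRIME_MYC]
    if red.interval.chrom != green.interval.chrom:
        raise LocusModelError("probe footprints must share a chromosome")
    if red.interval.overlap(green.interval) > 0:
        raise LocusModelError("probe footprints must not overlap")
    if red.interval.start >= green.interval.start:
        raise LocusModelError("5' (red) footprint must lie centromeric to the 3' (green) footprint")
    return red, green


# Default probe layout: a ~400 kb red block ending just centromeric of MYC and
# a ~400 kb green block beginning ~200 kb telomeric of it, on GRCh38-like chr8
# coordinates.  The vendor does not publish footprint coordinates; these are
# documented approximations — all pattern logic depends only on relative order.
MYC_GENE = GenomicInterval("chr8", 127_735_434, 127_742_951)
DEFAULT_RED_INTERVAL = GenomicInterval("chr8", 127_335_000, 127_735_000)
DEFAULT_GREEN_INTERVAL = GenomicInterval("chr8", 127_935_000, 128_335_000)

#: Window used to ask "does this SV touch the MYC locus?"
MYC_REGION = GenomicInterval("chr8", 127_200_000, 128_400_000)


def default_probes() -> list[ProbeFootprint]:
    return [
        ProbeFootprint(ProbeLabel.FIVE_PRIME_MYC, ProbeColor.RED, DEFAULT_RED_INTERVAL),
        ProbeFootprint(ProbeLabel.THREE_PRIME_MYC, ProbeColor.GREEN, DEFAULT_GREEN_INTERVAL),
    ]


# --------------------------------------------------------------------------- #
# junctions and copy-number segments
# --------------------------------------------------------------------------- #


class Side(enum.Enum):
    """Which reference flank a breakend retains.

    LEFT  — sequence centromeric of (i.e. before) the boundary is retained;
            the breakend position is the exclusive 0-based end of the piece.
    RIGHT — sequence telomeric of (i.e. from) the boundary is retained;
            the breakend position is the inclusive 0-based start of the piece.
    """

    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    side: Side

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise LocusModelError("breakend position must be >= 0")


@dataclass(frozen=True)
class Junction:
    """One novel adjacency joining two reference flanks."""

    breakend_a: Breakend
    breakend_b: Breakend
    partner_label: str | None = None
    event_id: str = ""

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.breakend_a, self.breakend_b)

    def overlaps(self, region: GenomicInterval) -> bool:
        return any(
            be.chrom == region.chrom and region.start <= be.pos <= region.end
            for be in self.breakends()
        )


@dataclass(frozen=True)
class CNSegment:
    interval: GenomicInterval
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise LocusModelError("copy number must be >= 0")


# --------------------------------------------------------------------------- #
# derivative chromosomes
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SegmentRef:
    """A reference interval used, possibly inverted, inside a derivative."""

    interval: GenomicInterval
    orientation: str = "+"  # "+" forward, "-" reverse

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise LocusModelError("orientation must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.interval)

    def leading_breakend(self) -> Breakend:
        """Reference flank exposed at the derivative-proximal end of the segment."""
        if self.orientation == "+":
            return Breakend(self.interval.chrom, self.interval.start, Side.RIGHT)
        return Breakend(self.interval.chrom, self.interval.end, Side.LEFT)

    def trailing_breakend(self) -> Breakend:
        """Reference flank exposed at the derivative-distal end of the segment."""
        if self.orientation == "+":
            return Breakend(self.interval.chrom, self.interval.end, Side.LEFT)
        return Breakend(self.interval.chrom, self.interval.start, Side.RIGHT)


@dataclass(frozen=True)
class DerivativeChromosome:
    name: str
    segments: tuple[SegmentRef, ...]

    def __init__(self, name: str, segments: Iterable[SegmentRef]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "segments", tuple(segments))
        if not self.segments:
            raise LocusModelError(f"derivative {name!r} must contain at least one segment")

    def __len__(self) -> int:
        return sum(len(s) for s in self.segments)


@dataclass(frozen=True)
class GenomeConfiguration:
    """One clone's set of derivative chromosomes plus its cell fraction."""

    derivatives: tuple[DerivativeChromosome, ...]
    clone_fraction: float = 1.0
    label: str = ""

    def __init__(
        self,
        derivatives: Iterable[DerivativeChromosome],
        clone_fraction: float = 1.0,
        label: str = "",
    ):
        object.__setattr__(self, "derivatives", tuple(derivatives))
        object.__setattr__(self, "clone_fraction", clone_fraction)
        object.__setattr__(self, "label", label)
        if not 0 < clone_fraction <= 1:
            raise LocusModelError("clone_fraction must be in (0, 1]")


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #


def build_diploid_reference(
    probes: Sequence[ProbeFootprint], flank: int = 1_000_000
) -> GenomeConfiguration:
    """Two identical homologs, each one contiguous reference segment spanning
    both probe footprints plus ``flank`` bases on each side."""
    if flank <= 0:
        raise LocusModelError("flank must be > 0")
    red, green = validate_probe_pair(probes)
    start = max(0, red.interval.start - flank)
    end = green.interval.end + flank
    span = GenomicInterval(red.interval.chrom, start, end)
    homologs = [
        DerivativeChromosome(f"homolog_{i + 1}", [SegmentRef(span)]) for i in range(2)
    ]
    return GenomeConfiguration(homologs, label="diploid_reference")


def assemble_derivative(
    junctions: Sequence[Junction],
    reference_segments: Sequence[SegmentRef],
    name: str = "der",
) -> DerivativeChromosome:
    """Join caller-ordered reference segments into a derivative chromosome.

    Each adjacency between consecutive segments must correspond to exactly one
    junction (in order): the junction's two breakends must equal the trailing
    flank of the left segment and the leading flank of the right segment.
    Genome-graph path inference is deliberately out of scope — the caller
    supplies the path.
    """
    segments = list(reference_segments)
    if not segments:
        raise AssemblyError("at least one segment is required")
    if len(junctions) != len(segments) - 1:
        raise AssemblyError(
            f"{len(segments)} segments require {len(segments) - 1} junctions, "
            f"got {len(junctions)}"
        )
    for i, junction in enumerate(junctions):
        expected = {segments[i].trailing_breakend(), segments[i + 1].leading_breakend()}
        if set(junction.breakends()) != expected:
            raise AssemblyError(
                f"junction {junction.event_id or i!r} does not join segment {i} "
                f"to segment {i + 1}: expected flanks {sorted(expected, key=str)}, "
                f"got {sorted(junction.breakends(), key=str)}"
            )
    return DerivativeChromosome(name, segments)


def footprint_copy_number(config: GenomeConfiguration, footprint: ProbeFootprint) -> float:
    """Fractional copy count of a probe footprint across all derivatives.

    Sum over every derivative segment of (overlap with the footprint) divided
    by the footprint length.  Additive over derivatives and invariant under
    segment subdivision by construction.
    """
    fp = footprint.interval
    total = 0
    for der in config.derivatives:
        for seg in der.segments:
            total += seg.interval.overlap(fp)
    return total / len(fp)
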