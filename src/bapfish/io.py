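"""Standard-format I/O: breakend VCF, probe BED, copy-number SEG.

VCF positions are 1-based; everything internal is 0-based half-open.  A
breakend that retains its LEFT flank maps to VCF POS equal to the internal
boundary (the last retained base, 1-based); a RIGHT-retaining breakend maps
to POS = boundary + 1 (the first retained base).

:func:`config_from_events` rebuilds a genome configuration from a set of
junctions and copy-number segments.  It deliberately does *not* infer
arbitrary genome-graph paths: it recognises the bounded event shapes the rest
of the package produces (reciprocal translocation, one-sided juxtaposition,
focal deletion, tandem/amplicon gain, templated insertion, whole-chromosome
gain) and raises on anything else.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .locus_model import (
    Breakend,
    CNSegment,
    DerivativeChromosome,
    GenomeConfiguration,
    GenomicInterval,
    Junction,
    LocusModelError,
    ProbeColor,
    ProbeFootprint,
    ProbeLabel,
    SegmentRef,
    Side,
    validate_probe_pair,
)


class IOError_(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------- #
# probe BED
# --------------------------------------------------------------------------- #


def read_probe_bed(path: str | Path) -> list[ProbeFootprint]:
    """4-column BED (chrom, start, end, label); labels must be the probe
    vocabulary and the red footprint must lie centromeric to the green one."""
    probes: list[ProbeFootprint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise IOError_(f"{path}:{lineno}: expected 4 BED columns, got {len(fields)}")
            chrom, start, end, label = fields[:4]
            try:
                probe_label = ProbeLabel(label)
            except ValueError:
                raise IOError_(
                    f"{path}:{lineno}: unknown probe label {label!r} "
                    f"(expected FIVE_PRIME_MYC or THREE_PRIME_MYC)"
                ) from None
            try:
                interval = GenomicInterval(chrom, int(start), int(end))
                probes.append(
                    ProbeFootprint(probe_label, {"FIVE_PRIME_MYC": ProbeColor.RED,
                                                 "THREE_PRIME_MYC": ProbeColor.GREEN}[label],
                                   interval)
                )
            except LocusModelError as exc:
                raise IOError_(f"{path}:{lineno}: {exc}") from exc
    try:
        validate_probe_pair(probes)
    except LocusModelError as exc:
        raise IOError_(f"{path}: {exc}") from exc
    return probes


def default_probe_bed_path() -> Path:
    from importlib import resources

    return Path(str(resources.files("bapfish.data").joinpath("myc_bap_probes.bed")))


# --------------------------------------------------------------------------- #
# SEG
# --------------------------------------------------------------------------- #

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "copy_number"]


def read_seg(path: str | Path) -> list[CNSegment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SEG_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: missing SEG columns {sorted(missing)}")
    return [
        CNSegment(GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.copy_number))
        for r in df.itertuples()
    ]


def write_seg(path: str | Path, segments: Sequence[CNSegment], sample: str = "sample") -> None:
    df = pd.DataFrame(
        [
            (sample, s.interval.chrom, s.interval.start, s.interval.end, s.copy_number)
            for s in segments
        ],
        columns=_SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# VCF breakends
# --------------------------------------------------------------------------- #

_BND_ALT_RE = re.compile(
    r"^(?P<t1>[ACGTNacgtn]*)(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<t2>[ACGTNacgtn]*)$"
)


def _parse_bnd_alt(alt: str, own_chrom: str, own_pos_1based: int) -> tuple[Breakend, Breakend]:
    """Decode one BND record into (own breakend, mate breakend)."""
    m = _BND_ALT_RE.match(alt)
    if not m or m.group("b1") != m.group("b2"):
        raise IOError_(f"malformed breakend ALT {alt!r}")
    if m.group("t1"):
        own = Breakend(own_chrom, own_pos_1based, Side.LEFT)
    elif m.group("t2"):
        own = Breakend(own_chrom, own_pos_1based - 1, Side.RIGHT)
    else:
        raise IOError_(f"breakend ALT {alt!r} lacks an anchoring base")
    mate_pos = int(m.group("pos"))
    if m.group("b1") == "[":
        mate = Breakend(m.group("chrom"), mate_pos - 1, Side.RIGHT)
    else:
        mate = Breakend(m.group("chrom"), mate_pos, Side.LEFT)
    return own, mate


def read_sv_vcf(path: str | Path) -> tuple[list[Junction], list[CNSegment]]:
    """Read BND mate pairs as junctions and symbolic DEL/DUP as CN segments.

    DEL means copy number 1 of the spanned interval (single-homolog event) and
    DUP copy number 3, unless the record carries an explicit ``CN`` INFO field.
    """
    junctions: list[Junction] = []
    cn_segments: list[CNSegment] = []
    pending: dict[str, tuple] = {}  # record id -> (own, mate, mate_id, partner)
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype == "BND":
                alt = rec.alts[0]
                try:
                    own, mate = _parse_bnd_alt(alt, rec.chrom, rec.pos)
                except IOError_ as exc:
                    raise IOError_(f"{path}: record {rec.id or rec.pos}: {exc}") from exc
                mate_id = rec.info.get("MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0]
                partner = rec.info.get("PARTNER") if "PARTNER" in rec.header.info else None
                pending[rec.id or f"{rec.chrom}:{rec.pos}:{alt}"] = (own, mate, mate_id, partner)
            elif svtype in ("DEL", "DUP"):
                end = rec.stop
                cn = rec.info.get("CN")
                if cn is None:
                    cn = 1 if svtype == "DEL" else 3
                cn_segments.append(
                    CNSegment(GenomicInterval(rec.chrom, rec.start, end), int(cn))
                )
            elif svtype is not None:
                raise IOError_(f"{path}: unsupported SVTYPE {svtype!r} (record {rec.id})")
    # pair mates
    seen: set[str] = set()
    for rec_id, (own, mate, mate_id, partner) in pending.items():
        if rec_id in seen:
            continue
        if mate_id is None or mate_id not in pending:
            # tolerate a mate expressed without MATEID if some record describes
            # the reciprocal coordinates; otherwise it is an orphan
            match = next(
                (
                    other_id
                    for other_id, (o2, m2, _, _) in pending.items()
                    if other_id != rec_id and other_id not in seen and o2 == mate and m2 == own
                ),
                None,
            )
            if match is None:
                raise IOError_(f"{path}: unmated breakend record {rec_id!r}")
            mate_id = match
        seen.update((rec_id, mate_id))
        event_id = rec_id.rsplit("_", 1)[0] if rec_id.rsplit("_", 1)[-1] in ("a", "b", "1", "2") else rec_id
        junctions.append(Junction(own, mate, partner_label=partner, event_id=event_id))
    return junctions, cn_segments


def _bnd_alt(own: Breakend, mate: Breakend) -> tuple[int, str]:
    """(1-based POS, ALT string) for one BND record."""
    if mate.side is Side.RIGHT:
        mate_str = f"[{mate.chrom}:{mate.pos + 1}["
    else:
        mate_str = f"]{mate.chrom}:{mate.pos}]"
    if own.side is Side.LEFT:
        return own.pos, f"N{mate_str}"
    return own.pos + 1, f"{mate_str}N"


def write_sv_vcf(
    path: str | Path,
    junctions: Sequence[Junction],
    cn_segments: Sequence[CNSegment],
    contig_lengths: Mapping[str, int],
) -> None:
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("MATEID", 1, "String", "ID of mate breakend")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("CN", 1, "Integer", "Copy number of the spanned interval")
    header.info.add("PARTNER", 1, "String", "Partner locus label")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, j in enumerate(junctions):
            base = j.event_id or f"jx{i}"
            for suffix, own, mate in (("a", j.breakend_a, j.breakend_b),
                                      ("b", j.breakend_b, j.breakend_a)):
                pos, alt = _bnd_alt(own, mate)
                rec = out.new_record(
                    contig=own.chrom, start=pos - 1, alleles=("N", alt),
                    id=f"{base}_{suffix}",
                )
                rec.info["SVTYPE"] = "BND"
                rec.info["MATEID"] = f"{base}_{'b' if suffix == 'a' else 'a'}"
                if j.partner_label:
                    rec.info["PARTNER"] = j.partner_label
                out.write(rec)
        for i, seg in enumerate(cn_segments):
            svtype = "DEL" if seg.copy_number < 2 else "DUP"
            rec = out.new_record(
                contig=seg.interval.chrom, start=seg.interval.start,
                stop=seg.interval.end, alleles=("N", f"<{svtype}>"), id=f"cnv{i}",
            )
            rec.info["SVTYPE"] = svtype
            rec.info["CN"] = seg.copy_number
            out.write(rec)


# --------------------------------------------------------------------------- #
# event-set -> genome configuration
# --------------------------------------------------------------------------- #


def _seg(chrom: str, start: int, end: int) -> SegmentRef:
    return SegmentRef(GenomicInterval(chrom, start, end))


def config_from_events(
    junctions: Sequence[Junction],
    cn_segments: Sequence[CNSegment],
    contig_lengths: Mapping[str, int],
    probe_chrom: str = "chr8",
    label: str = "from_events",
) -> GenomeConfiguration:
    """Rebuild a genome configuration from recognised event shapes."""
    chroms = {probe_chrom}
    for j in junctions:
        chroms.update((j.breakend_a.chrom, j.breakend_b.chrom))
    for c in cn_segments:
        chroms.add(c.interval.chrom)
    missing = chroms - set(contig_lengths)
    if missing:
        raise IOError_(f"no contig length known for {sorted(missing)}")

    homolog_count = {c: 2 for c in chroms}
    event_ders: list[DerivativeChromosome] = []
    junctions = list(junctions)
    gains = [c for c in cn_segments if c.copy_number > 2]
    losses = [c for c in cn_segments if c.copy_number < 2]

    # whole-chromosome gains first (they set the homolog baseline)
    for g in list(gains):
        if len(g.interval) >= 0.9 * contig_lengths[g.interval.chrom]:
            homolog_count[g.interval.chrom] += g.copy_number - 2
            gains.remove(g)

    def take_homolog(chrom: str) -> None:
        if homolog_count[chrom] <= 0:
            raise IOError_(f"event set consumes more {chrom} homologs than exist")
        homolog_count[chrom] -= 1

    # templated insertions: junction pairs sharing an insertion site
    used: set[int] = set()
    for i, j1 in enumerate(junctions):
        if i in used:
            continue
        for k, j2 in enumerate(junctions):
            if k <= i or k in used:
                continue
            pair = _match_insertion(j1, j2)
            if pair is None:
                continue
            chrom, site, src_chrom, a, b = pair
            take_homolog(chrom)
            event_ders.append(
                DerivativeChromosome(
                    f"ins_der_{len(event_ders)}",
                    [
                        _seg(chrom, 0, site),
                        _seg(src_chrom, a, b),
                        _seg(chrom, site, contig_lengths[chrom]),
                    ],
                )
            )
            for g in list(gains):  # consume the matching source gain, if any
                if g.interval.chrom == src_chrom and g.interval.start == a and g.interval.end == b:
                    gains.remove(g)
                    break
            used.update((i, k))
            break

    # reciprocal translocations
    for i, j1 in enumerate(junctions):
        if i in used:
            continue
        for k, j2 in enumerate(junctions):
            if k <= i or k in used:
                continue
            if _is_reciprocal(j1, j2):
                left = j1.breakend_a if j1.breakend_a.side is Side.LEFT else j1.breakend_b
                right = j1.breakend_a if left is j1.breakend_b else j1.breakend_b
                take_homolog(left.chrom)
                take_homolog(right.chrom)
                event_ders.append(
                    DerivativeChromosome(
                        f"der_a_{len(event_ders)}",
                        [_seg(left.chrom, 0, left.pos),
                         _seg(right.chrom, right.pos, contig_lengths[right.chrom])],
                    )
                )
                event_ders.append(
                    DerivativeChromosome(
                        f"der_b_{len(event_ders)}",
                        [_seg(right.chrom, 0, right.pos),
                         _seg(left.chrom, left.pos, contig_lengths[left.chrom])],
                    )
                )
                used.update((i, k))
                break

    # remaining single junctions
    for i, j in enumerate(junctions):
        if i in used:
            continue
        left = j.breakend_a if j.breakend_a.side is Side.LEFT else j.breakend_b
        right = j.breakend_a if left is j.breakend_b else j.breakend_b
        if left.side is not Side.LEFT or right.side is not Side.RIGHT:
            raise IOError_(
                f"junction {j.event_id!r}: unsupported breakend orientation "
                f"({j.breakend_a.side.value}/{j.breakend_b.side.value})"
            )
        if left.chrom == right.chrom and left.pos < right.pos:
            # simple deletion
            take_homolog(left.chrom)
            event_ders.append(
                DerivativeChromosome(
                    f"del_der_{len(event_ders)}",
                    [_seg(left.chrom, 0, left.pos),
                     _seg(left.chrom, right.pos, contig_lengths[left.chrom])],
                )
            )
        else:
            # a gain segment ending at the LEFT breakend marks an amplicon
            # juxtaposition (extra copy); otherwise an unbalanced translocation
            gain = next(
                (g for g in gains
                 if g.interval.chrom == left.chrom and g.interval.end == left.pos),
                None,
            )
            if gain is not None:
                gains.remove(gain)
                segments = [_seg(left.chrom, gain.interval.start, left.pos)]
                if right.chrom != left.chrom or right.pos != gain.interval.start:
                    segments.append(_seg(right.chrom, right.pos, contig_lengths[right.chrom]))
                event_ders.append(
                    DerivativeChromosome(f"gain_der_{len(event_ders)}", segments)
                )
            else:
                take_homolog(left.chrom)
                if right.chrom != left.chrom:
                    take_homolog(right.chrom)
                event_ders.append(
                    DerivativeChromosome(
                        f"der_{len(event_ders)}",
                        [_seg(left.chrom, 0, left.pos),
                         _seg(right.chrom, right.pos, contig_lengths[right.chrom])],
                    )
                )
        used.add(i)

    # remaining CN segments
    for g in gains:  # focal gain with no junction: free amplicon copy
        for _ in range(g.copy_number - 2):
            event_ders.append(
                DerivativeChromosome(
                    f"amp_der_{len(event_ders)}",
                    [_seg(g.interval.chrom, g.interval.start, g.interval.end)],
                )
            )
    for l in losses:
        take_homolog(l.interval.chrom)
        segments = []
        if l.interval.start > 0:
            segments.append(_seg(l.interval.chrom, 0, l.interval.start))
        if l.interval.end < contig_lengths[l.interval.chrom]:
            segments.append(_seg(l.interval.chrom, l.interval.end, contig_lengths[l.interval.chrom]))
        if not segments:
            continue  # whole-chromosome loss: homolog simply gone
        event_ders.append(DerivativeChromosome(f"del_der_{len(event_ders)}", segments))

    derivatives = []
    for chrom in sorted(chroms):
        for i in range(homolog_count[chrom]):
            derivatives.append(
                DerivativeChromosome(f"{chrom}_hom{i + 1}", [_seg(chrom, 0, contig_lengths[chrom])])
            )
    derivatives.extend(event_ders)
    return GenomeConfiguration(derivatives, label=label)


def _is_reciprocal(j1: Junction, j2: Junction) -> bool:
    def key(be: Breakend):
        return (be.chrom, be.pos)

    sides1 = {be.side for be in j1.breakends()}
    sides2 = {be.side for be in j2.breakends()}
    if sides1 != {Side.LEFT, Side.RIGHT} or sides2 != {Side.LEFT, Side.RIGHT}:
        return False
    pos1 = {key(be) for be in j1.breakends()}
    pos2 = {key(be) for be in j2.breakends()}
    if pos1 != pos2 or len(pos1) != 2:
        return False
    # the two junctions must retain opposite flanks at each position
    left1 = next(be for be in j1.breakends() if be.side is Side.LEFT)
    left2 = next(be for be in j2.breakends() if be.side is Side.LEFT)
    return key(left1) != key(left2)


def _match_insertion(j1: Junction, j2: Junction):
    """Detect a templated-insertion pair; returns (chrom, site, src_chrom, a, b)."""
    for ja, jb in ((j1, j2), (j2, j1)):
        # ja: (chrom, site, LEFT) -> (src, a, RIGHT);  jb: (src, b, LEFT) -> (chrom, site, RIGHT)
        for site_be, src_start in (ja.breakends(), reversed(ja.breakends())):
            if site_be.side is not Side.LEFT or src_start.side is not Side.RIGHT:
                continue
            for src_end, site_be2 in (jb.breakends(), reversed(jb.breakends())):
                if src_end.side is not Side.LEFT or site_be2.side is not Side.RIGHT:
                    continue
                if (
                    site_be2.chrom == site_be.chrom
                    and site_be2.pos == site_be.pos
                    and src_end.chrom == src_start.chrom
                    and src_start.pos < src_end.pos
                    and (src_start.chrom != site_be.chrom
                         or not src_start.pos <= site_be.pos <= src_end.pos)
                ):
                    return (site_be.chrom, site_be.pos, src_start.chrom,
                            src_start.pos, src_end.pos)
    return None
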