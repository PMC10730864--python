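"""The 14-case DLBCL/HGBCL validation cohort.

Each record pairs a verbatim ``nuc ish`` result with a minimal derivative
reconstruction of the sequencing-confirmed events at the *MYC* locus, plus
the partner gene, breakpoint-side annotation, juxtaposition-vs-copy-number
flag and MYC IHC status.  Breakpoint coordinates in the reconstructions are
illustrative (relative order faithful, base positions not published); the
cohort is therefore a consistency benchmark for the pipeline, not a source of
genomic truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

from .fish_sim import SimParams
from .interpret import ReconciliationReport, reconcile
from .iscn import parse_nuc_ish
from .locus_model import (
    Breakend,
    CNSegment,
    DerivativeChromosome,
    GenomeConfiguration,
    GenomicInterval,
    Junction,
    MYC_REGION,
    ProbeFootprint,
    SegmentRef,
    Side,
    default_probes,
)


class FixtureError(ValueError):
    """Corrupt or inconsistent fixture file."""


@dataclass(frozen=True)
class CaseRecord:
    case_id: int
    group: str  # printed pattern group: RF, GF or RGF
    nuc_ish: str
    partner: str | None
    juxtaposition: bool
    ihc_overexpressed: bool
    myc_breakpoint_side: str  # CENTROMERIC, TELOMERIC, GENIC or NA
    events: str
    junctions: tuple[Junction, ...]
    cn_segments: tuple[CNSegment, ...]
    derivatives: tuple[DerivativeChromosome, ...]
    clone_fraction: float

    def build_config(self) -> GenomeConfiguration:
        return GenomeConfiguration(
            self.derivatives,
            clone_fraction=self.clone_fraction,
            label=f"case_{self.case_id}",
        )

    def sv_overlapping_myc(self) -> bool:
        """Does any encoded junction or CN breakpoint touch the MYC region?"""
        if any(j.overlaps(MYC_REGION) for j in self.junctions):
            return True
        return any(c.interval.overlap(MYC_REGION) > 0 for c in self.cn_segments)


def _parse_junction(obj: dict) -> Junction:
    (ca, pa, sa), (cb, pb, sb) = obj["a"], obj["b"]
    return Junction(
        Breakend(ca, pa, Side(sa)),
        Breakend(cb, pb, Side(sb)),
        partner_label=obj.get("partner"),
        event_id=obj.get("id", ""),
    )


def _parse_derivative(obj: dict) -> DerivativeChromosome:
    return DerivativeChromosome(
        obj["name"],
        [
            SegmentRef(GenomicInterval(chrom, start, end), orient)
            for chrom, start, end, orient in obj["segments"]
        ],
    )


def load_cases(path: str | None = None) -> list[CaseRecord]:
    """Load (and checksum-verify) the packaged cohort, or a user-supplied file."""
    if path is None:
        text = resources.files("bapfish.data").joinpath("validation_cases.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    payload = json.loads(text)
    canonical = json.dumps(payload["cases"], sort_keys=True, separators=(",", ":"))
    digest = hashlib.sha256(canonical.encode()).hexdigest()
    if digest != payload.get("sha256"):
        raise FixtureError(
            f"fixture checksum mismatch: file says {payload.get('sha256')}, "
            f"content hashes to {digest}"
        )
    records = []
    for c in payload["cases"]:
        records.append(
            CaseRecord(
                case_id=c["case_id"],
                group=c["group"],
                nuc_ish=c["nuc_ish"],
                partner=c["partner"],
                juxtaposition=c["juxtaposition"],
                ihc_overexpressed=c["ihc_overexpressed"],
                myc_breakpoint_side=c["myc_breakpoint_side"],
                events=c["events"],
                junctions=tuple(_parse_junction(j) for j in c["junctions"]),
                cn_segments=tuple(
                    CNSegment(GenomicInterval(ch, s, e), cn)
                    for ch, s, e, cn in c["cn_segments"]
                ),
                derivatives=tuple(_parse_derivative(d) for d in c["derivatives"]),
                clone_fraction=c["clone_fraction"],
            )
        )
    if len(records) != 14:
        raise FixtureError(f"expected 14 case records, found {len(records)}")
    return records


def validate_concordance(
    record: CaseRecord,
    params: SimParams | None = None,
    probes: list[ProbeFootprint] | None = None,
) -> ReconciliationReport:
    """Run the full pipeline on one record: parse its nomenclature, simulate
    its reconstruction, and compare observed with predicted pattern class."""
    observed = parse_nuc_ish(record.nuc_ish)
    config = record.build_config()
    events = tuple(
        f"{j.event_id or 'junction'}: {j.breakend_a.chrom}:{j.breakend_a.pos} "
        f"({j.breakend_a.side.value}) :: {j.breakend_b.chrom}:{j.breakend_b.pos} "
        f"({j.breakend_b.side.value})"
        + (f" [{j.partner_label}]" if j.partner_label else "")
        for j in record.junctions
    )
    return reconcile(
        observed,
        config,
        probes or default_probes(),
        params or SimParams(),
        sv_events=events,
    )
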