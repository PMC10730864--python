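"""Build a derivative chromosome and simulate its break-apart signal pattern.

An unbalanced translocation joins the chromosome-8 sequence centromeric of a
breakpoint (telomeric of MYC, between the probe footprints) to a partner
locus.  The derivative keeps the red (5') footprint but loses the green (3')
one, so next to the intact homolog's fusion signal it shows an isolated red:
the classic RF-type pattern.
"""

from bapfish import (
    Breakend,
    DerivativeChromosome,
    GenomicInterval,
    GenomeConfiguration,
    Junction,
    SegmentRef,
    Side,
    assemble_derivative,
    classify_pattern,
    default_probes,
    format_nuc_ish,
    pattern_to_iscn,
    simulate_signals,
)

probes = default_probes()
CHR8_LEN = 145_138_636
bp = 127_800_000  # between MYC and the green footprint
partner_bp = 50_000_000

der = assemble_derivative(
    junctions=[
        Junction(
            Breakend("chr8", bp, Side.LEFT),
            Breakend("partner", partner_bp, Side.RIGHT),
            partner_label="partner",
            event_id="t(8;partner)",
        )
    ],
    reference_segments=[
        SegmentRef(GenomicInterval("chr8", 0, bp)),
        SegmentRef(GenomicInterval("partner", partner_bp, 100_000_000)),
    ],
    name="der(8)t(8;partner)",
)
intact = DerivativeChromosome("chr8_homolog", [SegmentRef(GenomicInterval("chr8", 0, CHR8_LEN))])
config = GenomeConfiguration([intact, der])

pattern = simulate_signals(config, probes)
print(f"isolated red:   {pattern.n_red_isolated}")
print(f"isolated green: {pattern.n_green_isolated}")
print(f"fusions:        {pattern.n_fusion}")
print(f"class:          {classify_pattern(pattern).value}")
print(f"as nuc ish:     {format_nuc_ish(pattern_to_iscn(pattern))}")
# Expect 1R / 0G / 1F -> RF; the nomenclature writer emits the matching
# '(5'MYCx2,3'MYCx1)(5'MYC con 3'MYCx1)' form.
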