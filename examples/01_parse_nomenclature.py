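"""Parse ISCN 'nuc ish' strings and derive the signal summary.

The fusion rule: a 'con' term counts colocalised red+green pairs directly;
a 'sep' term counts separated pairs, so fusions = min(R, G) - sep; without a
relation term every possible pair is assumed fused.  Isolated counts are the
probe totals minus fusions, evaluated at both ends of any count range.
"""

from bapfish import classify_result, format_nuc_ish, parse_nuc_ish, summarize_clone

examples = [
    "nuc ish(5′MYCx2,3′MYCx1)(5′MYC con 3′MYCx1)[100]",      # unbalanced: extra red
    "nuc ish(MYCx2)(5′MYC sep 3′MYCx1)[96/100]",             # balanced separation
    "nuc ish(5’MYCx1,3’MYCx2)(5’MYC con 3’MYCx1)[68/100]",   # unbalanced: extra green
    "nuc ish(MYCx2)[100]",                                   # normal
]

for text in examples:
    result = parse_nuc_ish(text)
    summary = summarize_clone(result.clones[0])
    cls = classify_result(result)
    print(f"input:     {text}")
    print(f"canonical: {format_nuc_ish(result)}")
    print(
        f"signals:   R={summary.r_total.lo}-{summary.r_total.hi} "
        f"G={summary.g_total.lo}-{summary.g_total.hi} "
        f"F={summary.fusion.lo}-{summary.fusion.hi} "
        f"isolated R={summary.r_isolated.lo} isolated G={summary.g_isolated.lo}"
    )
    print(f"class:     {cls.value}\n")

# The class names follow break-apart convention: RF = isolated red without
# isolated green, GF the reverse, RGF = both (the classic positive pattern).
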