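"""Parsing, summarising and re-emitting ISCN interphase ("nuc ish") nomenclature
for the two-probe *MYC* break-apart assay.

Scope is deliberately the interphase dialect used for break-apart results:
probe count terms like ``(5'MYCx2~3,3'MYCx1-2)``, colocalisation/separation
relation terms (``con`` / ``sep``), bracketed cell counts ``[97/100]`` and
multiple clones separated by ``/``.  Published strings mix typographic prime
marks (U+2032, U+2019), tilde variants (U+223C) and hyphen ranges, with
inconsistent interior whitespace; the parser normalises all of these, and
:func:`format_nuc_ish` re-emits a canonical ASCII dialect.

The scientific core of the module is :func:`summarize_clone`: from probe
totals and the con/sep relation it derives how many fusion (F) signals and how
many isolated red/green signals a clone exhibits —

* a ``con`` term counts colocalised red+green pairs directly: F = con count;
* a ``sep`` term counts separated pairs: F = min(R, G) − sep count;
* without a relation term every possible pair is assumed colocalised:
  F = min(R, G)

— and then ``isolated red = R − F``, ``isolated green = G − F``, evaluated at
both endpoints of any count range.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence


class IscnError(ValueError):
    """Base error for nomenclature handling."""


class IscnSyntaxError(IscnError):
    """Unparseable token; carries the character offset in the input string."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class IscnSemanticError(IscnError):
    """Well-formed but self-contradictory nomenclature."""


# --------------------------------------------------------------------------- #
# data model
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CountInterval:
    """Closed integer range; a plain count is carried as lo == hi."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo < 0 or self.lo > self.hi:
            raise IscnSemanticError(f"invalid count range [{self.lo},{self.hi}]")

    @classmethod
    def exact(cls, n: int) -> "CountInterval":
        return cls(n, n)

    def __add__(self, other: "CountInterval") -> "CountInterval":
        return CountInterval(self.lo + other.lo, self.hi + other.hi)

    def is_exact(self) -> bool:
        return self.lo == self.hi


class ProbeTarget(enum.Enum):
    FIVE_PRIME = "5'MYC"
    THREE_PRIME = "3'MYC"
    BOTH = "MYC"  # the bare "MYC" token: both probes share the count


class RelationKind(enum.Enum):
    CON = "con"
    SEP = "sep"


@dataclass(frozen=True)
class ProbeCount:
    probe: ProbeTarget
    count: CountInterval


@dataclass(frozen=True)
class RelationTerm:
    kind: RelationKind
    count: CountInterval


@dataclass(frozen=True)
class NucIshClone:
    probe_counts: tuple[ProbeCount, ...]
    relations: tuple[RelationTerm, ...]
    cells_observed: int
    cells_total: int

    def __post_init__(self) -> None:
        if not self.probe_counts:
            raise IscnSemanticError("clone must carry at least one probe count")
        if not (0 < self.cells_observed <= self.cells_total):
            raise IscnSemanticError(
                f"cell count [{self.cells_observed}/{self.cells_total}] "
                "requires 0 < observed <= total"
            )
        kinds = {r.kind for r in self.relations}
        if kinds == {RelationKind.CON, RelationKind.SEP}:
            raise IscnSemanticError("a clone may not mix con and sep relation terms")


@dataclass(frozen=True)
class NucIshResult:
    clones: tuple[NucIshClone, ...]
    raw_text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.clones:
            raise IscnSemanticError("result must contain at least one clone")
        total = self.clones[0].cells_total
        observed = sum(c.cells_observed for c in self.clones)
        if observed > total:
            raise IscnSemanticError(
                f"clone cell counts sum to {observed} > {total} cells scored"
            )


@dataclass(frozen=True)
class SignalSummary:
    """Derived red/green/fusion signal totals for one clone."""

    r_total: CountInterval
    g_total: CountInterval
    fusion: CountInterval
    r_isolated: CountInterval
    g_isolated: CountInterval


# --------------------------------------------------------------------------- #
# normalisation and tokenising
# --------------------------------------------------------------------------- #

_PRIME_CHARS = {"′", "’", "'"}
_TILDE_CHARS = {"∼", "~"}


def _normalize(text: str) -> tuple[str, list[int]]:
    """Map typographic variants to a canonical alphabet and drop whitespace.

    Returns the normalised string plus, for each normalised character, the
    offset of the character it came from in the original input (used to make
    syntax errors point at the user's text, not ours).
    """
    out: list[str] = []
    offsets: list[int] = []
    for i, ch in enumerate(text):
        if ch.isspace():
            continue
        if ch in _PRIME_CHARS:
            ch = "'"
        elif ch in _TILDE_CHARS:
            ch = "~"
        out.append(ch)
        offsets.append(i)
    return "".join(out), offsets


@dataclass(frozen=True)
class _Token:
    kind: str  # PROBE, REL, COUNT, LPAREN, RPAREN, LBRACK, RBRACK, COMMA, SLASH, INT
    value: object
    offset: int  # offset in the *original* string


_COUNT_RE = re.compile(r"x(\d+)(?:[~-](\d+))?")
_INT_RE = re.compile(r"\d+")


def _tokenize(norm: str, offsets: list[int], raw: str) -> Iterator[_Token]:
    i = 0
    n = len(norm)
    while i < n:
        orig = offsets[i]
        ch = norm[i]
        if ch == "(":
            yield _Token("LPAREN", "(", orig); i += 1
        elif ch == ")":
            yield _Token("RPAREN", ")", orig); i += 1
        elif ch == "[":
            yield _Token("LBRACK", "[", orig); i += 1
        elif ch == "]":
            yield _Token("RBRACK", "]", orig); i += 1
        elif ch == ",":
            yield _Token("COMMA", ",", orig); i += 1
        elif ch == "/":
            yield _Token("SLASH", "/", orig); i += 1
        elif norm.startswith("5'MYC", i):
            yield _Token("PROBE", ProbeTarget.FIVE_PRIME, orig); i += 5
        elif norm.startswith("3'MYC", i):
            yield _Token("PROBE", ProbeTarget.THREE_PRIME, orig); i += 5
        elif norm.startswith("MYC", i):
            yield _Token("PROBE", ProbeTarget.BOTH, orig); i += 3
        elif norm.startswith("con", i):
            yield _Token("REL", RelationKind.CON, orig); i += 3
        elif norm.startswith("sep", i):
            yield _Token("REL", RelationKind.SEP, orig); i += 3
        elif ch == "x":
            m = _COUNT_RE.match(norm, i)
            if not m:
                raise IscnSyntaxError("expected a count after 'x'", orig)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if hi < lo:  # descending hyphen range like x2-1
                raise IscnSyntaxError(f"descending count range x{lo}-{hi}", orig)
            yield _Token("COUNT", CountInterval(lo, hi), orig)
            i = m.end()
        elif ch.isdigit():
            m = _INT_RE.match(norm, i)
            yield _Token("INT", int(m.group()), orig)
            i = m.end()
        else:
            raise IscnSyntaxError(f"unexpected character {raw[orig]!r}", orig)


class _TokenStream:
    def __init__(self, tokens: Sequence[_Token], end_offset: int):
        self._tokens = list(tokens)
        self._pos = 0
        self._end = end_offset

    def peek(self) -> _Token | None:
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise IscnSyntaxError("unexpected end of input", self._end)
        self._pos += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise IscnSyntaxError(f"expected {kind}, found {tok.value!r}", tok.offset)
        return tok

    def at_end(self) -> bool:
        return self._pos >= len(self._tokens)


# --------------------------------------------------------------------------- #
# parser
# --------------------------------------------------------------------------- #


def parse_nuc_ish(text: str) -> NucIshResult:
    """Parse a ``nuc ish`` result string into its clone structure.

    Accepts the typographic variants found in published tables (unicode prime
    and tilde marks, hyphen ranges, interior whitespace, a stray comma after
    ``nuc ish``) and the shared-multiplier form ``(5'MYC,3'MYC)x2~4``.
    """
    if not text or not text.strip():
        raise IscnSyntaxError("empty input", 0)
    norm, offsets = _normalize(text)
    if not norm.startswith("nucish"):
        raise IscnSyntaxError("result must start with 'nuc ish'", offsets[0] if offsets else 0)
    body_start = len("nucish")
    if body_start < len(norm) and norm[body_start] == ",":  # tolerated stray comma
        body_start += 1
    tokens = list(_tokenize(norm[body_start:], offsets[body_start:], text))
    stream = _TokenStream(tokens, len(text))

    clones = []
    while True:
        clones.append(_parse_clone(stream))
        if stream.at_end():
            break
        stream.expect("SLASH")
    return NucIshResult(tuple(clones), raw_text=text)


def _parse_clone(stream: _TokenStream) -> NucIshClone:
    probe_counts: list[ProbeCount] = []
    relations: list[RelationTerm] = []
    saw_group = False
    while True:
        tok = stream.peek()
        if tok is None or tok.kind != "LPAREN":
            break
        saw_group = True
        _parse_group(stream, probe_counts, relations)
    if not saw_group:
        tok = stream.peek()
        raise IscnSyntaxError(
            "expected a probe group '('", tok.offset if tok else stream._end
        )
    observed, total = _parse_cells(stream)
    return NucIshClone(tuple(probe_counts), tuple(relations), observed, total)


def _parse_group(
    stream: _TokenStream,
    probe_counts: list[ProbeCount],
    relations: list[RelationTerm],
) -> None:
    stream.expect("LPAREN")
    first = stream.expect("PROBE")
    tok = stream.peek()
    if tok is not None and tok.kind == "REL":
        # relation group: (5'MYC con 3'MYCx1~2)
        kind = stream.next().value
        stream.expect("PROBE")
        count_tok = stream.expect("COUNT")
        stream.expect("RPAREN")
        relations.append(RelationTerm(kind, count_tok.value))
        return
    # probe-count group: (5'MYCx2,3'MYCx1) or shared-multiplier (5'MYC,3'MYC)x2~4
    entries: list[tuple[ProbeTarget, CountInterval | None]] = []
    probe = first.value
    while True:
        tok = stream.peek()
        count = None
        if tok is not None and tok.kind == "COUNT":
            count = stream.next().value
        entries.append((probe, count))
        tok = stream.next()
        if tok.kind == "RPAREN":
            break
        if tok.kind != "COMMA":
            raise IscnSyntaxError(f"expected ',' or ')', found {tok.value!r}", tok.offset)
        probe = stream.expect("PROBE").value
    tok = stream.peek()
    shared: CountInterval | None = None
    if tok is not None and tok.kind == "COUNT":
        shared = stream.next().value
    for probe, count in entries:
        if count is None:
            count = shared
        if count is None:
            raise IscnSyntaxError(
                f"probe {probe.value} has no count and no shared multiplier",
                tok.offset if tok else stream._end,
            )
        probe_counts.append(ProbeCount(probe, count))


def _parse_cells(stream: _TokenStream) -> tuple[int, int]:
    stream.expect("LBRACK")
    observed = stream.expect("INT").value
    tok = stream.next()
    if tok.kind == "RBRACK":
        return observed, observed  # "[100]" means 100/100
    if tok.kind != "SLASH":
        raise IscnSyntaxError(f"expected '/' or ']', found {tok.value!r}", tok.offset)
    total = stream.expect("INT").value
    stream.expect("RBRACK")
    return observed, total


# --------------------------------------------------------------------------- #
# signal summary
# --------------------------------------------------------------------------- #


def _probe_totals(clone: NucIshClone) -> tuple[CountInterval, CountInterval]:
    r = CountInterval.exact(0)
    g = CountInterval.exact(0)
    for pc in clone.probe_counts:
        if pc.probe in (ProbeTarget.FIVE_PRIME, ProbeTarget.BOTH):
            r = r + pc.count
        if pc.probe in (ProbeTarget.THREE_PRIME, ProbeTarget.BOTH):
            g = g + pc.count
    return r, g


def summarize_clone(clone: NucIshClone, ploidy: int = 2) -> SignalSummary:
    """Derive fusion and isolated red/green signal counts for one clone.

    Evaluated independently at the low and high endpoint of every count range;
    a negative isolated count at either endpoint means the nomenclature is
    internally inconsistent and raises :class:`IscnSemanticError`.
    """
    r, g = _probe_totals(clone)
    con = [t for t in clone.relations if t.kind is RelationKind.CON]
    sep = [t for t in clone.relations if t.kind is RelationKind.SEP]
    min_rg = CountInterval(min(r.lo, g.lo), min(r.hi, g.hi))
    if con:
        fusion_lo = sum(t.count.lo for t in con)
        fusion_hi = sum(t.count.hi for t in con)
    elif sep:
        fusion_lo = min_rg.lo - sum(t.count.lo for t in sep)
        fusion_hi = min_rg.hi - sum(t.count.hi for t in sep)
    else:
        fusion_lo, fusion_hi = min_rg.lo, min_rg.hi
    r_iso_lo, r_iso_hi = r.lo - fusion_lo, r.hi - fusion_hi
    g_iso_lo, g_iso_hi = g.lo - fusion_lo, g.hi - fusion_hi
    if min(fusion_lo, fusion_hi, r_iso_lo, r_iso_hi, g_iso_lo, g_iso_hi) < 0:
        raise IscnSemanticError(
            "inconsistent nomenclature: derived a negative fusion or isolated "
            f"signal count (R={r}, G={g}, relations={clone.relations})"
        )
    try:
        return SignalSummary(
            r_total=r,
            g_total=g,
            fusion=CountInterval(fusion_lo, fusion_hi),
            r_isolated=CountInterval(r_iso_lo, r_iso_hi),
            g_isolated=CountInterval(g_iso_lo, g_iso_hi),
        )
    except IscnSemanticError as exc:  # endpoint inversion, e.g. sep range too wide
        raise IscnSemanticError(f"inconsistent nomenclature: {exc}") from exc


# --------------------------------------------------------------------------- #
# canonical writer
# --------------------------------------------------------------------------- #


def _format_count(count: CountInterval) -> str:
    return f"x{count.lo}" if count.is_exact() else f"x{count.lo}~{count.hi}"


def _format_clone(clone: NucIshClone) -> str:
    parts = []
    probe_strs = [f"{pc.probe.value}{_format_count(pc.count)}" for pc in clone.probe_counts]
    parts.append(f"({','.join(probe_strs)})")
    for rel in clone.relations:
        parts.append(f"(5'MYC {rel.kind.value} 3'MYC{_format_count(rel.count)})")
    if clone.cells_observed == clone.cells_total:
        parts.append(f"[{clone.cells_observed}]")
    else:
        parts.append(f"[{clone.cells_observed}/{clone.cells_total}]")
    return "".join(parts)


def format_nuc_ish(result: NucIshResult) -> str:
    """Emit the canonical ASCII dialect: ASCII apostrophes, '~' ranges, no
    interior whitespace except around con/sep.  ``parse_nuc_ish(format_nuc_ish(x))``
    is structurally equal to ``x`` (shared multipliers are emitted expanded)."""
    return "nuc ish" + "/".join(_format_clone(c) for c in result.clones)
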