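"""Clinical-style interpretation and observed-vs-predicted reconciliation.

Two complementary tasks live here:

* :func:`interpret_result` renders the recommended interpretation for a
  break-apart pattern class.  Unbalanced (RF/GF) patterns are the interesting
  branch: most harbour a genuine structural variant juxtaposing *MYC* with a
  partner locus, so with no ancillary data they are reported "likely positive"
  with confirmatory testing recommended, while a confirmed juxtaposition
  upgrades to positive and a confirmed pure copy-number change is explicitly
  *not* classified as a rearrangement.  The branch table is data-driven
  (JSON) so laboratories can adjust it.

* :func:`reconcile` runs the signal simulator on a sequencing-derived genome
  reconstruction and compares the predicted pattern class with the class
  observed in the reported nomenclature, including the copy-number direction
  that explains an unbalanced result (material 5' of *MYC* at higher copy
  number for RF, 3' for GF).

:func:`survey_percentages` is a small utility for tallying practice-survey
counts with half-up integer rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

from .fish_sim import PatternClass, SimParams, classify_result, simulate_signals
from .iscn import NucIshResult
from .locus_model import (
    GenomeConfiguration,
    ProbeFootprint,
    ProbeLabel,
    footprint_copy_number,
)


class InterpretError(ValueError):
    pass


@dataclass(frozen=True)
class AncillaryFindings:
    """Optional orthogonal results; ``None`` means not performed/unknown."""

    dfish_igh_positive: bool | None = None
    ihc_overexpressed: bool | None = None
    partner_is_ig: bool | None = None


@dataclass(frozen=True)
class Interpretation:
    category: str
    narrative: str
    recommended_tests: tuple[str, ...] = ()


CATEGORIES = (
    "NEGATIVE_WITH_FN_CAVEAT",
    "POSITIVE_MYC_REARRANGEMENT",
    "LIKELY_POSITIVE_RECOMMEND_TESTING",
    "CN_ALTERATION_NOT_CLASSIFIED_AS_R",
    "AMBIGUOUS_RECOMMEND_TESTING",
)


def load_rules(path: str | None = None) -> dict:
    """Load the interpretation decision table (packaged default or a user file)."""
    if path is None:
        text = resources.files("bapfish.data").joinpath("interpretation_rules.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = json.loads(text)["rules"]
    for pattern, branch in rules.items():
        leaves = branch.values() if "category" not in branch else [branch]
        for leaf in leaves:
            if leaf["category"] not in CATEGORIES:
                raise InterpretError(
                    f"unknown interpretation category {leaf['category']!r} for {pattern}"
                )
    return rules


_DEFAULT_RULES = load_rules()


def interpret_result(
    pattern: PatternClass,
    ancillary: AncillaryFindings | None = None,
    has_confirmed_juxtaposition: bool | None = None,
    rules: dict | None = None,
) -> Interpretation:
    """Interpretation for a pattern class given what else is known.

    ``has_confirmed_juxtaposition`` is a tri-state input, never an inference:
    ``True`` — orthogonal testing confirmed a gene-juxtaposing structural
    variant; ``False`` — testing confirmed a pure copy-number change;
    ``None`` — not investigated.  A positive IG/MYC dual-fusion result counts
    as a confirmed juxtaposition.
    """
    rules = rules if rules is not None else _DEFAULT_RULES
    ancillary = ancillary or AncillaryFindings()
    branch = rules[pattern.value]
    if "category" not in branch:  # unbalanced patterns: three-way branch
        confirmed = has_confirmed_juxtaposition
        if confirmed is None and ancillary.dfish_igh_positive:
            confirmed = True
        key = "unknown" if confirmed is None else ("juxtaposition" if confirmed else "pure_cn")
        branch = branch[key]
    return Interpretation(
        category=branch["category"],
        narrative=branch["narrative"],
        recommended_tests=tuple(branch.get("recommended_tests", ())),
    )


# --------------------------------------------------------------------------- #
# reconciliation
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ReconciliationReport:
    observed_class: PatternClass
    predicted_class: PatternClass
    concordant: bool
    cn_explanation: str
    cn_five_prime: float
    cn_three_prime: float
    sv_events: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "observed_class": self.observed_class.value,
            "predicted_class": self.predicted_class.value,
            "concordant": self.concordant,
            "cn_explanation": self.cn_explanation,
            "cn_five_prime": self.cn_five_prime,
            "cn_three_prime": self.cn_three_prime,
            "sv_events": list(self.sv_events),
        }


def _cn_explanation(cn5: float, cn3: float) -> str:
    if cn5 > cn3:
        rel = "exceeds"
    elif cn5 < cn3:
        rel = "is below"
    else:
        rel = "equals"
    return (
        f"copy number of the 5' (red) footprint is {cn5:.2f} and {rel} "
        f"the 3' (green) footprint at {cn3:.2f}"
    )


def reconcile(
    observed: NucIshResult,
    config: GenomeConfiguration,
    probes: Sequence[ProbeFootprint],
    params: SimParams | None = None,
    sv_events: Sequence[str] = (),
    ploidy: int = 2,
) -> ReconciliationReport:
    """Compare the observed nomenclature with the pattern the reconstruction
    predicts, and state the footprint copy-number asymmetry that explains an
    unbalanced result."""
    from .fish_sim import classify_pattern

    params = params or SimParams()
    observed_class = classify_result(observed, ploidy)
    predicted = simulate_signals(config, list(probes), params)
    predicted_class = classify_pattern(predicted, ploidy)
    by_label = {p.label: p for p in probes}
    cn5 = footprint_copy_number(config, by_label[ProbeLabel.FIVE_PRIME_MYC])
    cn3 = footprint_copy_number(config, by_label[ProbeLabel.THREE_PRIME_MYC])
    return ReconciliationReport(
        observed_class=observed_class,
        predicted_class=predicted_class,
        concordant=observed_class is predicted_class,
        cn_explanation=_cn_explanation(cn5, cn3),
        cn_five_prime=cn5,
        cn_three_prime=cn3,
        sv_events=tuple(sv_events),
    )


# --------------------------------------------------------------------------- #
# survey tallies
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SurveyTally:
    item: str
    k: int
    n: int
    percent: int


def survey_percentages(items: Sequence[tuple[str, int, int]]) -> list[SurveyTally]:
    """Tally (label, k, n) counts as half-up-rounded integer percentages."""
    tallies = []
    for label, k, n in items:
        if n <= 0:
            raise InterpretError(f"{label!r}: denominator must be > 0")
        if not 0 <= k <= n:
            raise InterpretError(f"{label!r}: need 0 <= k <= n, got {k}/{n}")
        percent = int(
            (Decimal(100 * k) / Decimal(n)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        )
        tallies.append(SurveyTally(label, k, n, percent))
    return tallies
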