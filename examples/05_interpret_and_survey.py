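"""Render interpretations for each pattern class and tally the practice survey.

The survey (54 laboratories) illustrates why unbalanced patterns need a
standard interpretation: practice varies widely, and most laboratories call
them equivocal.
"""

import json
from importlib import resources

from bapfish import interpret_result, survey_percentages
from bapfish.fish_sim import PatternClass

for pattern in (PatternClass.NORMAL, PatternClass.RGF, PatternClass.RF, PatternClass.GF):
    result = interpret_result(pattern)
    print(f"{pattern.value:>9}: {result.category}")
    if result.recommended_tests:
        print(f"           recommend: {', '.join(result.recommended_tests)}")

print()
payload = json.loads(
    resources.files("bapfish.data").joinpath("survey_counts.json").read_text()
)
for tally in survey_percentages([(i["label"], i["k"], i["n"]) for i in payload["items"]]):
    print(f"{tally.percent:>3}%  ({tally.k}/{tally.n})  {tally.item}")
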