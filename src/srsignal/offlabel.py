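"""Label-expectedness annotation for consensus signals.

A signal is off-label iff its drug is present in the label knowledge base
and the signal's preferred term is not in that drug's labeled set. Drugs
absent from the knowledge base yield "undetermined" — never a silent
"labeled". Annotation is pure set membership on standardized PT strings.
"""

from __future__ import annotations

from typing import Sequence

from .records import LabelKnowledge
from .signals import SignalResult

LABELED = "labeled"
OFF_LABEL = "off_label"
UNDETERMINED = "undetermined"


def annotate(drug: str, pt: str, labels: LabelKnowledge) -> str:
    if not labels.knows(drug):
        return UNDETERMINED
    return LABELED if pt in labels.labeled_pts(drug) else OFF_LABEL


def flag_offlabel(
    results: Sequence[SignalResult], labels: LabelKnowledge
) -> list[SignalResult]:
    """Annotate each signal's ``offlabel`` field in place; returns the list."""
    for result in results:
        result.offlabel = annotate(result.drug, result.pt, labels)
    return list(results)
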