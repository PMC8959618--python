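"""Bundled miniature dictionaries: a 15-drug antipsychotic roster (7 typical,
8 atypical) with a few raw-name variants, a ~40-term reaction vocabulary, and
a curated label knowledge base. These are fixtures for testing and the
synthetic pipeline, not a real terminology."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import load_drug_dictionary, load_label_knowledge, load_term_dictionary
from .records import DrugDictionary, LabelKnowledge, TermDictionary


def fixture_path(name: str) -> Path:
    return Path(resources.files("srsignal.resources") / name)


def bundled_drug_dictionary() -> DrugDictionary:
    return load_drug_dictionary(fixture_path("drug_dictionary.csv"))


def bundled_term_dictionary() -> TermDictionary:
    return load_term_dictionary(fixture_path("term_dictionary.csv"))


def bundled_label_knowledge() -> LabelKnowledge:
    return load_label_knowledge(fixture_path("label_knowledge.csv"))


def bundled_dictionaries() -> tuple[DrugDictionary, TermDictionary, LabelKnowledge]:
    return (
        bundled_drug_dictionary(),
        bundled_term_dictionary(),
        bundled_label_knowledge(),
    )
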