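"""Loaders for the bundled data: original questionnaire, the published
original-vs-suggested comparison table, and the demo emotion lexicon."""

from __future__ import annotations

import json
from importlib import resources

from .emotion_intensity import EmotionLexicon
from .questionnaire_revision import Questionnaire, RevisionRules, Subclass


# Configurable stand-ins for the study's (unpublished) thesaurus-expansion
# and pain-condition lists; disjoint from the bundled questionnaire words.
DEFAULT_THESAURUS = [
    "agony", "ache", "twinge", "pang", "discomfort",
    "distress", "suffering", "misery", "affliction", "torment",
]

DEFAULT_CONDITIONS = [
    "migraine", "arthritis", "fibromyalgia", "sciatica", "toothache",
    "backache", "headache", "cramps", "gout", "neuropathy",
]


def _read_data(name: str) -> str:
    return resources.files("painlex.data").joinpath(name).read_text(encoding="utf-8")


def load_original_mpq() -> Questionnaire:
    """The bundled 78-descriptor / 20-subclass original questionnaire."""
    return Questionnaire.from_json(json.loads(_read_data("mpq_original.json")))


def load_table1_fixture() -> dict:
    """Raw comparison-table fixture (counts, intensities, suggested column)."""
    return json.loads(_read_data("table1_fixture.json"))


def table1_rules(fixture: dict | None = None) -> RevisionRules:
    """Revision rules configured with the study's published choices."""
    fx = fixture or load_table1_fixture()
    return RevisionRules(
        decile=0.10,
        context_removals=[tuple(t) for t in fx["context_removals"]],
        additions_assignment=dict(fx["additions_assignment"]),
        psychological_selection=list(fx["psychological_selection"]),
        sentence_frame=fx["sentence_frame"],
        reorder_direction="ascending",
        psych_count_envelope=tuple(fx["psychological_envelope"]["count"]),
        psych_intensity_envelope=tuple(fx["psychological_envelope"]["intensity"]),
    )


def table1_intensities(fixture: dict | None = None) -> dict:
    """Merged intensity map over original, new, and psychological words."""
    fx = fixture or load_table1_fixture()
    out = dict(fx["original_intensities"])
    for word, stats in fx["new_word_stats"].items():
        out[word] = stats["intensity"]
    for word, stats in fx["psychological_stats"].items():
        out.setdefault(word, stats["intensity"])
    return out


def suggested_questionnaire(fixture: dict | None = None):
    """Published suggested questionnaire; returns (Questionnaire, flags).

    ``flags`` maps subclass name -> reordered? (None for the new one).
    """
    fx = fixture or load_table1_fixture()
    q = Questionnaire(
        subclasses=[
            Subclass(name=sc["name"], class_label=sc["class_label"], descriptors=list(sc["descriptors"]))
            for sc in fx["suggested"]
        ]
    )
    flags = {sc["name"]: sc["reordered"] for sc in fx["suggested"]}
    return q, flags


def demo_emotion_lexicon() -> EmotionLexicon:
    """Small built-in demonstration lexicon (token/channel/intensity TSV)."""
    with resources.as_file(resources.files("painlex.data").joinpath("demo_emotion_lexicon.tsv")) as p:
        return EmotionLexicon.from_tsv(p)
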