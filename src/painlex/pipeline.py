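"""Two-round pipeline orchestration with stage manifests.

Round 1: clean -> hop-limited relevance -> manual exclusions -> sarcasm
-> embeddings -> neighbor extraction -> pruning -> provenance merge.
Round 2: clean -> descriptor+condition filter -> sarcasm -> counts ->
intensities -> questionnaire revision. Each stage records n_in / n_out /
n_removed (conservation asserted) plus a provenance hash of its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import corpus_io, embedding_association, sarcasm_filter
from .corpus_io import FilterConfig, Post
from .embedding_association import EmbeddingConfig
from .emotion_intensity import EmotionLexicon, descriptor_stats_table
from .questionnaire_revision import (
    Questionnaire,
    RevisionRules,
    count_descriptors,
    revise_questionnaire,
)
from .sarcasm_filter import SarcasmConfig
from .stemming import stem

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage empties the pipeline (CLI exit code 3)."""


class ConfigError(ValueError):
    """Raised on invalid pipeline configuration (CLI exit code 2)."""


def percentage(part: float, whole: float, ndigits: int = 2) -> float:
    """Manifest percentage: 100 * part / whole rounded to ``ndigits``."""
    if whole == 0:
        raise ValueError("percentage undefined for a zero denominator")
    return round(100.0 * part / whole, ndigits)


def _posts_hash(posts: Sequence[Post]) -> str:
    h = hashlib.sha256()
    for p in posts:
        h.update(p.id.encode("utf-8"))
        h.update(b"\x00")
    return h.hexdigest()[:16]


@dataclass
class StageManifest:
    """Bookkeeping of counts in/out at every pipeline stage."""

    stages: list = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, breakdown: dict | None = None,
               input_hash: str = "") -> None:
        n_removed = n_in - n_out
        if n_removed < 0:
            raise ValueError(f"stage {stage!r}: n_out exceeds n_in")
        entry = {
            "stage": stage,
            "n_in": n_in,
            "n_out": n_out,
            "n_removed": n_removed,
            "breakdown": breakdown or {},
            "input_hash": input_hash,
        }
        assert entry["n_in"] == entry["n_out"] + entry["n_removed"]
        self.stages.append(entry)
        logger.info("stage %-18s in=%d out=%d removed=%d", stage, n_in, n_out, n_removed)

    def removal_percentage(self, stage: str, of_total: int | None = None, ndigits: int = 2) -> float:
        for entry in self.stages:
            if entry["stage"] == stage:
                total = of_total if of_total is not None else entry["n_in"]
                return percentage(entry["n_removed"], total, ndigits)
        raise KeyError(f"no stage named {stage!r}")

    def to_json(self, path=None):
        payload = {"stages": self.stages}
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return payload


@dataclass
class PipelineConfig:
    """All per-module configs plus the single global seed."""

    filter: FilterConfig
    sarcasm: SarcasmConfig
    embedding: EmbeddingConfig
    rules: RevisionRules
    lexicon: EmotionLexicon
    mpq_keywords: list = field(default_factory=list)
    thesaurus_keywords: list = field(default_factory=list)
    antonym_map: dict = field(default_factory=dict)
    stoplist: list = field(default_factory=list)
    seed: int = 0
    intensity_mode: str = "neg_max"


def run_round1(posts: Sequence[Post], cfg: PipelineConfig):
    """Preliminary round; returns (kept posts, tagged candidates, manifest).

    Candidates are the pruned, provenance-tagged associated words over
    all round-1 keywords (original + thesaurus-derived).
    """
    manifest = StageManifest()
    in_hash = _posts_hash(posts)
    cleaned = corpus_io.clean_posts(posts)
    manifest.record("clean", len(posts), len(cleaned), input_hash=in_hash)

    keywords = list(cfg.mpq_keywords) + list(cfg.thesaurus_keywords)
    if not keywords:
        raise ConfigError("round 1 requires a non-empty keyword list")
    fcfg = FilterConfig(
        descriptor_list=keywords,
        hop_limit=cfg.filter.hop_limit,
        window=cfg.filter.window,
        manual_exclusions=cfg.filter.manual_exclusions,
    )
    relevant = [p for p in cleaned if corpus_io.relevance_filter_round1(p, fcfg)]
    manifest.record("relevance_hop", len(cleaned), len(relevant),
                    breakdown={"hop_limit": fcfg.hop_limit}, input_hash=_posts_hash(cleaned))

    kept, excluded, _log = corpus_io.apply_manual_exclusions(relevant, fcfg)
    manifest.record("manual_exclusions", len(relevant), len(kept),
                    input_hash=_posts_hash(relevant))

    kept, removed_sarcastic, _scores = sarcasm_filter.filter_sarcastic(kept, cfg.sarcasm)
    manifest.record("sarcasm", len(kept) + len(removed_sarcastic), len(kept),
                    breakdown={"threshold": cfg.sarcasm.threshold},
                    input_hash=_posts_hash(kept + removed_sarcastic))
    if not kept:
        raise PipelineError("no posts survive round-1 filtering; nothing to embed")

    model = embedding_association.train_embeddings(kept, cfg.embedding)
    root_stems = {stem(tok) for kw in keywords for tok in kw.split()}
    per_keyword = {}
    for kw in keywords:
        cands = embedding_association.associated_words(model, kw, cfg.embedding)
        pruned, _plog = embedding_association.prune_candidates(
            cands, root_stems, cfg.antonym_map, cfg.stoplist
        )
        per_keyword[kw] = pruned
    tagged, prov_counts = embedding_association.merge_and_tag_provenance(
        per_keyword, cfg.mpq_keywords, cfg.thesaurus_keywords
    )
    manifest.record("associate", len(kept), len(kept),
                    breakdown={"candidates": len(tagged), **prov_counts},
                    input_hash=_posts_hash(kept))
    return kept, tagged, manifest


def run_round2(
    posts: Sequence[Post],
    cfg: PipelineConfig,
    expanded_keywords: Sequence[str],
    original: Questionnaire,
):
    """Final round; returns (final posts, stats, revised, report, manifest)."""
    if not cfg.filter.condition_list:
        raise ConfigError("round 2 requires a non-empty pain-condition list")
    if not expanded_keywords:
        raise ConfigError("round 2 requires the expanded keyword list")
    manifest = StageManifest()
    cleaned = corpus_io.clean_posts(posts)
    manifest.record("clean", len(posts), len(cleaned), input_hash=_posts_hash(posts))

    fcfg = FilterConfig(
        descriptor_list=list(expanded_keywords),
        condition_list=cfg.filter.condition_list,
        hop_limit=cfg.filter.hop_limit,
        manual_exclusions=cfg.filter.manual_exclusions,
    )
    included = [p for p in cleaned if corpus_io.relevance_filter_round2(p, fcfg)]
    manifest.record("descriptor_condition", len(cleaned), len(included),
                    input_hash=_posts_hash(cleaned))

    kept, removed_sarcastic, _scores = sarcasm_filter.filter_sarcastic(included, cfg.sarcasm)
    manifest.record("sarcasm", len(included), len(kept),
                    breakdown={"threshold": cfg.sarcasm.threshold},
                    input_hash=_posts_hash(included))
    if not kept:
        raise PipelineError("no posts survive round-2 filtering")

    original_descriptors = original.all_descriptors()
    counts = count_descriptors(kept, original_descriptors)
    new_words = [w for w in expanded_keywords if w not in original_descriptors]
    stats_rows = descriptor_stats_table(
        kept, original_descriptors + new_words, cfg.lexicon, mode=cfg.intensity_mode
    )
    stats = {s.descriptor: s for s in stats_rows}
    intensities = {
        s.descriptor: (s.intensity if s.intensity is not None else 0.0) for s in stats_rows
    }
    psych_stats = {w: stats[w] for w in cfg.rules.psychological_selection if w in stats}
    revised, report = revise_questionnaire(
        original, counts, stats, psych_stats, intensities, cfg.rules
    )
    manifest.record("revision", len(kept), len(kept),
                    breakdown={"removed": len(report.removed), "added": len(report.added)},
                    input_hash=_posts_hash(kept))
    return kept, stats_rows, revised, report, manifest
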