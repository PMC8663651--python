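"""Lexicon-based emotion channel scoring and per-descriptor pain intensity.

Five fixed channels (anger, fear, sadness, joy, valence) are scored per
post as the maximum lexicon intensity over the post's tokens; a
configurable mapping collapses them to a single [0,1] pain intensity,
which is averaged over all posts containing a descriptor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Sequence

from .corpus_io import Post, contains_phrase

CHANNELS = ("anger", "fear", "sadness", "joy", "valence")

INTENSITY_MODES = ("neg_max", "one_minus_valence", "blend")

DEFAULT_BLEND_WEIGHTS = {"anger": 0.25, "fear": 0.25, "sadness": 0.25, "joy": 0.0, "valence": 0.25}


@dataclass
class EmotionLexicon:
    """token -> channel -> intensity in [0,1]; unknown channels rejected."""

    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        for token, channels in self.entries.items():
            for channel, intensity in channels.items():
                if channel not in CHANNELS:
                    raise ValueError(f"unknown emotion channel {channel!r} for {token!r}")
                if not 0.0 <= intensity <= 1.0:
                    raise ValueError(f"intensity out of [0,1] for {token!r}.{channel}: {intensity}")

    @classmethod
    def from_tsv(cls, path) -> "EmotionLexicon":
        """Load a (token, channel, intensity) TSV, one entry per line."""
        entries: dict[str, dict] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{line_no}: expected 3 tab-separated fields")
                token, channel, intensity = parts
                entries.setdefault(token.lower(), {})[channel] = float(intensity)
        return cls(entries=entries)

    def to_tsv(self, path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for token in sorted(self.entries):
                for channel, intensity in sorted(self.entries[token].items()):
                    fh.write(f"{token}\t{channel}\t{intensity}\n")


@dataclass
class EmotionScores:
    post_id: str
    anger: float = 0.0
    fear: float = 0.0
    sadness: float = 0.0
    joy: float = 0.0
    valence: float = 0.0

    def __post_init__(self):
        for channel in CHANNELS:
            value = getattr(self, channel)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{channel} out of [0,1]: {value}")

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in CHANNELS}


@dataclass
class DescriptorStats:
    """A descriptor with its corpus prevalence and aggregated intensity."""

    descriptor: str
    count: int
    intensity: float | None = None
    subclass: str | None = None

    def __post_init__(self):
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.intensity is not None and not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity out of [0,1]: {self.intensity}")


def score_emotions(post: Post, lexicon: EmotionLexicon) -> EmotionScores:
    """Per-channel maximum lexicon intensity over the whole post.

    Whole-post scope, no sentence splitting; channels with no lexicon
    token present score 0.
    """
    best = {c: 0.0 for c in CHANNELS}
    for token in post.tokens:
        entry = lexicon.entries.get(token)
        if entry:
            for channel, intensity in entry.items():
                if intensity > best[channel]:
                    best[channel] = intensity
    return EmotionScores(post_id=post.id, **best)


def pain_intensity(scores: EmotionScores, mode: str = "neg_max", weights: dict | None = None) -> float:
    """Collapse the five channels to one [0,1] pain intensity.

    Modes: ``neg_max`` = max(anger, fear, sadness); ``one_minus_valence``;
    ``blend`` = weighted mean over channels (weights must sum to a
    positive total).
    """
    if mode == "neg_max":
        return max(scores.anger, scores.fear, scores.sadness)
    if mode == "one_minus_valence":
        return 1.0 - scores.valence
    if mode == "blend":
        w = weights or DEFAULT_BLEND_WEIGHTS
        total = sum(w.values())
        if total <= 0:
            raise ValueError("blend weights must sum to a positive total")
        return sum(w.get(c, 0.0) * getattr(scores, c) for c in CHANNELS) / total
    raise ValueError(f"unknown pain-intensity mode {mode!r}; choose from {INTENSITY_MODES}")


def descriptor_intensity(
    posts_containing: Sequence[Post],
    lexicon: EmotionLexicon,
    mode: str = "neg_max",
    weights: dict | None = None,
) -> float:
    """Arithmetic mean of per-post pain intensity over the containing posts.

    Zero containing posts is undefined (an error), never 0.
    """
    if not posts_containing:
        raise ValueError("descriptor_intensity undefined for zero containing posts")
    return fmean(
        pain_intensity(score_emotions(p, lexicon), mode=mode, weights=weights)
        for p in posts_containing
    )


def descriptor_stats_table(
    posts: Sequence[Post],
    descriptors: Iterable[str],
    lexicon: EmotionLexicon,
    mode: str = "neg_max",
) -> list:
    """Count + mean intensity per descriptor over a cleaned corpus.

    Descriptors absent from the corpus get count 0 and intensity None.
    """
    out = []
    for descriptor in descriptors:
        containing = [p for p in posts if contains_phrase(p.tokens, descriptor)]
        if containing:
            out.append(
                DescriptorStats(
                    descriptor=descriptor,
                    count=len(containing),
                    intensity=descriptor_intensity(containing, lexicon, mode=mode),
                )
            )
        else:
            out.append(DescriptorStats(descriptor=descriptor, count=0, intensity=None))
    return out


def write_stats_csv(stats: Iterable[DescriptorStats], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["descriptor", "count", "intensity", "subclass"])
        for s in stats:
            writer.writerow(
                [s.descriptor, s.count, "" if s.intensity is None else f"{s.intensity:.6f}", s.subclass or ""]
            )
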