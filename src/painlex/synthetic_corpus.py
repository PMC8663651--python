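"""Seeded generator of social-media-like corpora with planted structure.

Every downstream stage (cleaning, hop filtering, sarcasm removal,
embedding association, counting, intensity aggregation) is tested against
corpora produced here, whose hidden labels and analytic expectations are
known exactly. Post text is a bag of tokens rendered with single spaces
plus optional @username / URL noise; hidden labels travel in a sidecar
structure and never leak into the text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable

import numpy as np

from .stemming import stem

NOISE_PREFIX = "nz"
_PLATFORMS = ("twitter", "facebook", "instagram", "youtube")


@dataclass
class PlantedLexicon:
    """Vocabulary with known structure planted into generated posts.

    ``associates`` maps each root descriptor to ``(word, propensity)``
    pairs: the associate co-occurs (adjacent to its root) in that
    fraction of the root's posts. Associate words must not share a stem
    with any root so planted novelty stays detectable downstream.
    """

    root_descriptors: list
    associates: dict = field(default_factory=dict)
    conditions: list = field(default_factory=list)
    emotion_words: dict = field(default_factory=dict)
    sarcasm_markers: list = field(default_factory=list)

    def __post_init__(self):
        root_stems = {stem(tok) for r in self.root_descriptors for tok in r.split()}
        for root, pairs in self.associates.items():
            if root not in self.root_descriptors:
                raise ValueError(f"associate map references unknown root {root!r}")
            for word, prop in pairs:
                if not 0.0 <= prop <= 1.0:
                    raise ValueError(f"propensity for {word!r} out of [0,1]: {prop}")
                if word in self.root_descriptors or stem(word) in root_stems:
                    raise ValueError(
                        f"associate {word!r} collides with a root descriptor stem"
                    )
        for channel, pairs in self.emotion_words.items():
            for word, intensity in pairs:
                if not 0.0 <= intensity <= 1.0:
                    raise ValueError(f"intensity for {word!r} out of [0,1]: {intensity}")
        for term in self.all_terms():
            if any(t == "pain" or t.startswith(NOISE_PREFIX) for t in term.split()):
                raise ValueError(f"planted term {term!r} collides with reserved vocabulary")

    def flat_emotion_words(self) -> list:
        return [w for pairs in self.emotion_words.values() for (w, _i) in pairs]

    def all_terms(self) -> list:
        terms = list(self.root_descriptors)
        terms += [w for pairs in self.associates.values() for (w, _p) in pairs]
        terms += list(self.conditions)
        terms += self.flat_emotion_words()
        terms += list(self.sarcasm_markers)
        return terms


@dataclass
class CorpusConfig:
    """Parameters of the generative model; one seed drives one rng stream."""

    n_posts: int
    planted_lexicon: PlantedLexicon
    p_contains_pain: float = 0.7
    p_sarcastic: float = 0.05
    p_username: float = 0.3
    p_url: float = 0.2
    noise_vocab_size: int = 500
    post_length_range: tuple = (5, 12)
    seed: int = 0
    # Extra knobs beyond the minimal surface: how often a relevant post
    # carries a condition mention / an emotion word.
    p_condition: float = 0.5
    p_emotion_word: float = 0.5

    def __post_init__(self):
        for name in ("p_contains_pain", "p_sarcastic", "p_username", "p_url",
                     "p_condition", "p_emotion_word"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        lo, hi = self.post_length_range
        if lo < 3 or hi < lo:
            raise ValueError(f"post_length_range invalid: {self.post_length_range}")
        if self.noise_vocab_size < 1:
            raise ValueError("noise_vocab_size must be positive")


@dataclass
class PostLabels:
    """Hidden generation labels for one post (sidecar, not in the text)."""

    post_id: str
    relevant: bool
    sarcastic: bool
    root: str | None = None
    associates_present: list = field(default_factory=list)
    condition: str | None = None
    emotion_word: str | None = None
    marker: str | None = None


@dataclass
class SyntheticCorpus:
    posts: list
    labels: list


def _choice(rng: np.random.Generator, items):
    return items[int(rng.integers(len(items)))]


def generate_corpus(config: CorpusConfig):
    """Generate ``config.n_posts`` posts plus hidden labels.

    Relevant posts contain ``pain`` with a uniformly chosen root
    descriptor adjacent to it; each of the root's associates is planted
    next to the root with its propensity; a condition and an emotion word
    are planted with ``p_condition`` / ``p_emotion_word``. Sarcastic
    posts always carry a sarcasm marker. Remaining length is filled with
    ``nz<k>`` noise tokens.
    """
    if config.n_posts <= 0:
        return SyntheticCorpus(posts=[], labels=[])
    from .corpus_io import Post  # local import to avoid a cycle

    lex = config.planted_lexicon
    rng = np.random.default_rng(config.seed)
    lo, hi = config.post_length_range
    posts, labels = [], []
    flat_emotions = lex.flat_emotion_words()
    for i in range(config.n_posts):
        pid = f"p{i:06d}"
        relevant = bool(rng.random() < config.p_contains_pain) and bool(lex.root_descriptors)
        sarcastic = bool(rng.random() < config.p_sarcastic) and bool(lex.sarcasm_markers)
        lab = PostLabels(post_id=pid, relevant=relevant, sarcastic=sarcastic)
        core: list[str] = []
        if relevant:
            root = _choice(rng, lex.root_descriptors)
            lab.root = root
            core.append("pain")
            core.extend(root.split())
            for word, prop in lex.associates.get(root, []):
                if rng.random() < prop:
                    core.extend(word.split())
                    lab.associates_present.append(word)
            if lex.conditions and rng.random() < config.p_condition:
                cond = _choice(rng, lex.conditions)
                lab.condition = cond
                core.extend(cond.split())
            if flat_emotions and rng.random() < config.p_emotion_word:
                emo = _choice(rng, flat_emotions)
                lab.emotion_word = emo
                core.append(emo)
        if sarcastic:
            marker = _choice(rng, lex.sarcasm_markers)
            lab.marker = marker
            core.extend(marker.split())
        length = int(rng.integers(lo, hi + 1))
        n_noise = max(0, length - len(core))
        noise_ids = rng.integers(config.noise_vocab_size, size=n_noise)
        tokens = core + [f"{NOISE_PREFIX}{int(k)}" for k in noise_ids]

        parts = list(tokens)
        if rng.random() < config.p_username:
            parts.insert(0, f"@user{int(rng.integers(10_000))}")
        if rng.random() < config.p_url:
            parts.append(f"https://t.co/{int(rng.integers(10_000)):x}")
        if sarcastic:
            parts.append("!!")
        platform = _choice(rng, _PLATFORMS)
        day = int(rng.integers(364))
        # deterministic pseudo-timestamp inside the study year
        ts = f"2019-{1 + day // 31:02d}-{1 + day % 28:02d}T{int(rng.integers(24)):02d}:00:00+00:00"
        posts.append(Post(id=pid, platform=platform, timestamp=ts, text=" ".join(parts)))
        labels.append(lab)
    return SyntheticCorpus(posts=posts, labels=labels)


def _core_size_distribution(config: CorpusConfig) -> dict:
    """Exact distribution of the planted (non-noise) token count per post."""
    lex = config.planted_lexicon
    pp = config.p_contains_pain if lex.root_descriptors else 0.0
    ps = config.p_sarcastic if lex.sarcasm_markers else 0.0
    flat_emotions = lex.flat_emotion_words()

    relevant_dist: dict[int, float] = {0: 1.0 - pp}
    if pp > 0:
        n_roots = len(lex.root_descriptors)
        for root in lex.root_descriptors:
            base = 1 + len(root.split())  # "pain" + root tokens
            dist = {base: 1.0}
            for word, prop in lex.associates.get(root, []):
                nxt: dict[int, float] = {}
                for size, p in dist.items():
                    nxt[size] = nxt.get(size, 0.0) + p * (1.0 - prop)
                    k = size + len(word.split())
                    nxt[k] = nxt.get(k, 0.0) + p * prop
                dist = nxt
            if lex.conditions:
                pc = config.p_condition
                nxt = {}
                for size, p in dist.items():
                    nxt[size] = nxt.get(size, 0.0) + p * (1.0 - pc)
                    for cond in lex.conditions:
                        k = size + len(cond.split())
                        nxt[k] = nxt.get(k, 0.0) + p * pc / len(lex.conditions)
                dist = nxt
            if flat_emotions:
                pe = config.p_emotion_word
                nxt = {}
                for size, p in dist.items():
                    nxt[size] = nxt.get(size, 0.0) + p * (1.0 - pe)
                    nxt[size + 1] = nxt.get(size + 1, 0.0) + p * pe
                dist = nxt
            for size, p in dist.items():
                relevant_dist[size] = relevant_dist.get(size, 0.0) + pp * p / n_roots

    total: dict[int, float] = {}
    for size, p in relevant_dist.items():
        total[size] = total.get(size, 0.0) + p * (1.0 - ps)
        if ps > 0:
            for marker in lex.sarcasm_markers:
                k = size + len(marker.split())
                total[k] = total.get(k, 0.0) + p * ps / len(lex.sarcasm_markers)
    return total


def expected_counts(config: CorpusConfig) -> dict:
    """Analytic expected post counts per word under the generative model.

    Returns a map covering ``pain``, every planted term, and every noise
    token; anything absent from the map has expectation 0. Serves as the
    independent oracle for descriptor-count tests.
    """
    lex = config.planted_lexicon
    n = max(config.n_posts, 0)
    pp = config.p_contains_pain if lex.root_descriptors else 0.0
    out: dict[str, float] = {}
    out["pain"] = n * pp
    n_roots = max(len(lex.root_descriptors), 1)
    for root in lex.root_descriptors:
        out[root] = out.get(root, 0.0) + n * pp / n_roots
        for word, prop in lex.associates.get(root, []):
            out[word] = out.get(word, 0.0) + n * pp * prop / n_roots
    for cond in lex.conditions:
        out[cond] = out.get(cond, 0.0) + n * pp * config.p_condition / len(lex.conditions)
    flat_emotions = lex.flat_emotion_words()
    for word in flat_emotions:
        out[word] = out.get(word, 0.0) + n * pp * config.p_emotion_word / len(flat_emotions)
    ps = config.p_sarcastic if lex.sarcasm_markers else 0.0
    for marker in lex.sarcasm_markers:
        out[marker] = out.get(marker, 0.0) + n * ps / len(lex.sarcasm_markers)

    # Noise words: P(present) = E_C E_len [1 - (1 - 1/V)^max(0, len - C)]
    if n > 0:
        v = config.noise_vocab_size
        lo, hi = config.post_length_range
        lengths = range(lo, hi + 1)
        core_dist = _core_size_distribution(config)
        p_present = 0.0
        for size, p in core_dist.items():
            for length in lengths:
                slots = max(0, length - size)
                p_present += p * (1.0 - (1.0 - 1.0 / v) ** slots) / len(lengths)
        for k in range(v):
            out[f"{NOISE_PREFIX}{k}"] = n * p_present
    return out


# ---------------------------------------------------------------------------
# Sidecar I/O


def write_labels_jsonl(labels: Iterable[PostLabels], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for lab in labels:
            fh.write(json.dumps(vars(lab)) + "\n")


def read_labels_jsonl(path) -> list:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(PostLabels(**json.loads(line)))
    return out
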