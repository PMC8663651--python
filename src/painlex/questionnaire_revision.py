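"""Questionnaire revision: thresholding, removals, additions, reordering.

The engine takes per-descriptor counts and intensities and applies, in
order: a bottom-decile prevalence threshold, rule-tagged removals
(low use / drifted context), placement of qualifying new words into
their assigned subclasses, construction of the psychological subclass,
and a stable intensity-based reordering of every subclass. All human
judgments of the original study (context removals, subclass assignment,
psychological selection) enter as configuration with machine-checked
preconditions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Post, contains_phrase

CLASS_LABELS = ("sensory", "affective", "evaluative", "supplementary", "psychological")


@dataclass
class Subclass:
    name: str
    class_label: str
    descriptors: list

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError(f"duplicate descriptor within subclass {self.name!r}")


@dataclass
class Questionnaire:
    """Ordered subclasses of ordered descriptors."""

    subclasses: list

    def all_descriptors(self) -> list:
        return [d for sc in self.subclasses for d in sc.descriptors]

    def subclass(self, name: str) -> Subclass:
        for sc in self.subclasses:
            if sc.name == name:
                return sc
        raise KeyError(f"no subclass named {name!r}")

    def to_json(self, path=None):
        payload = {
            "subclasses": [
                {"name": sc.name, "class_label": sc.class_label, "descriptors": list(sc.descriptors)}
                for sc in self.subclasses
            ]
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source) -> "Questionnaire":
        if isinstance(source, (str, Path)):
            source = json.loads(Path(source).read_text(encoding="utf-8"))
        return cls(
            subclasses=[
                Subclass(name=sc["name"], class_label=sc["class_label"], descriptors=list(sc["descriptors"]))
                for sc in source["subclasses"]
            ]
        )

    def to_markdown(self) -> str:
        lines = []
        for sc in self.subclasses:
            lines.append(f"## {sc.name} ({sc.class_label})")
            lines.extend(f"- {d}" for d in sc.descriptors)
            lines.append("")
        return "\n".join(lines)


@dataclass
class RevisionRules:
    """Configuration of the revision; defaults mirror the published study."""

    decile: float = 0.10
    context_removals: list = field(default_factory=list)
    additions_assignment: dict = field(default_factory=dict)
    psychological_selection: list = field(default_factory=list)
    sentence_frame: str = "My pain makes me ___"
    reorder_direction: str = "ascending"
    psych_count_envelope: tuple | None = None
    psych_intensity_envelope: tuple | None = None

    def __post_init__(self):
        if not 0.0 < self.decile < 1.0:
            raise ValueError(f"decile must be in (0,1), got {self.decile}")
        if self.reorder_direction not in ("ascending", "descending"):
            raise ValueError(f"reorder_direction must be ascending|descending")


@dataclass
class RevisionReport:
    threshold_used: int
    removed: list
    added: list
    new_subclasses: list
    reordered_subclasses: list
    per_subclass_diffs: dict

    def to_json(self, path=None):
        payload = {
            "threshold_used": self.threshold_used,
            "removed": [list(t) for t in self.removed],
            "added": [list(t) for t in self.added],
            "new_subclasses": list(self.new_subclasses),
            "reordered_subclasses": list(self.reordered_subclasses),
            "per_subclass_diffs": self.per_subclass_diffs,
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return payload

    def to_markdown(self) -> str:
        lines = [f"Threshold: {self.threshold_used}", "", "Removed:"]
        lines += [f"- {d} ({rule})" for d, rule in self.removed]
        lines += ["", "Added:"]
        lines += [f"- {d} -> {sc}" for d, sc in self.added]
        lines += ["", "New subclasses: " + ", ".join(self.new_subclasses)]
        lines += ["Reordered subclasses: " + ", ".join(self.reordered_subclasses)]
        return "\n".join(lines)


def count_descriptors(posts: Sequence[Post], descriptors: Iterable[str]) -> dict:
    """Post-level prevalence: number of posts containing each descriptor.

    Phrase-aware and post-level — a descriptor occurring twice in one
    post contributes 1.
    """
    out = {}
    for descriptor in descriptors:
        out[descriptor] = sum(1 for p in posts if contains_phrase(p.tokens, descriptor))
    return out


def derive_threshold(original_counts: Mapping[str, int], decile: float = 0.10):
    """Bottom-decile prevalence threshold; returns (threshold, bottom_set).

    ``k = ceil(decile * n)`` lowest-count descriptors form the bottom
    set (ties broken alphabetically; a tie straddling the boundary pulls
    all tied members in). The threshold is the smallest count strictly
    above every bottom-set count, so descriptors with ``count <
    threshold`` fail the prevalence criterion. A fully tied input is
    degenerate: a warning is emitted and the threshold is that count + 1.
    """
    n = len(original_counts)
    if n == 0:
        raise ValueError("original_counts must be non-empty")
    ranked = sorted(original_counts.items(), key=lambda kv: (kv[1], kv[0]))
    k = math.ceil(decile * n)
    while k < n and ranked[k][1] == ranked[k - 1][1]:
        k += 1
    if k >= n:
        warnings.warn("all counts tied: threshold is degenerate", stacklevel=2)
        tied = ranked[0][1]
        return tied + 1, [name for name, _c in ranked[: math.ceil(decile * n)]]
    threshold = ranked[k][1]
    return threshold, [name for name, _c in ranked[:k]]


def apply_removal_rules(
    original: Questionnaire,
    counts: Mapping[str, int],
    threshold: int,
    rules: RevisionRules,
):
    """Tag and strip removals; returns (removals, survivors).

    ``removals`` is a list of (descriptor, rule) with rule ``low_use``
    (count < threshold) or ``context`` (configured drifted-context list);
    ``survivors`` is the questionnaire with those descriptors dropped,
    structure otherwise intact.
    """
    descriptors = original.all_descriptors()
    missing = [d for d in descriptors if d not in counts]
    if missing:
        raise ValueError(f"counts missing for descriptors: {missing}")
    context_words = []
    for entry in rules.context_removals:
        word = entry[0] if isinstance(entry, (tuple, list)) else entry
        if word not in descriptors:
            raise ValueError(f"context removal names unknown descriptor {word!r}")
        context_words.append(word)
    removals = []
    removed_set = set()
    for d in descriptors:
        if counts[d] < threshold:
            removals.append((d, "low_use"))
            removed_set.add(d)
    for w in context_words:
        if w not in removed_set:
            removals.append((w, "context"))
            removed_set.add(w)
    survivors = Questionnaire(
        subclasses=[
            Subclass(
                name=sc.name,
                class_label=sc.class_label,
                descriptors=[d for d in sc.descriptors if d not in removed_set],
            )
            for sc in original.subclasses
        ]
    )
    return removals, survivors


def apply_addition_rules(
    candidate_stats: Mapping[str, "object"],
    threshold: int,
    rules: RevisionRules,
):
    """Validate and place new words; returns list of (word, subclass).

    Every configured addition must meet the prevalence threshold in
    ``candidate_stats`` (word -> object with ``count``); a violation is
    an error, which makes the prevalence criterion machine-checked.
    """
    additions = []
    for word, subclass in rules.additions_assignment.items():
        if word not in candidate_stats:
            raise ValueError(f"no stats for configured addition {word!r}")
        count = getattr(candidate_stats[word], "count", None)
        if count is None:
            count = candidate_stats[word]["count"]
        if count < threshold:
            raise ValueError(
                f"addition {word!r} fails the prevalence criterion: count {count} < {threshold}"
            )
        additions.append((word, subclass))
    return additions


def build_psychological_subclass(stats: Mapping[str, "object"], rules: RevisionRules) -> Subclass:
    """Ordered psychological subclass from the configured selection.

    Order follows the selection list (the published word forms fit the
    sentence frame). When envelopes are configured, counts/intensities
    outside them raise a validation warning.
    """
    if not rules.psychological_selection:
        warnings.warn("empty psychological selection: empty subclass", stacklevel=2)
        return Subclass(name="Psychological", class_label="psychological", descriptors=[])
    for word in rules.psychological_selection:
        if word not in stats:
            raise ValueError(f"no stats for psychological selection {word!r}")
        entry = stats[word]
        count = getattr(entry, "count", None)
        intensity = getattr(entry, "intensity", None)
        if count is None and isinstance(entry, Mapping):
            count, intensity = entry["count"], entry["intensity"]
        if rules.psych_count_envelope is not None:
            lo, hi = rules.psych_count_envelope
            if not lo <= count <= hi:
                warnings.warn(f"count for {word!r} outside envelope [{lo}, {hi}]: {count}", stacklevel=2)
        if rules.psych_intensity_envelope is not None and intensity is not None:
            lo, hi = rules.psych_intensity_envelope
            if not lo <= intensity <= hi:
                warnings.warn(
                    f"intensity for {word!r} outside envelope [{lo}, {hi}]: {intensity}", stacklevel=2
                )
    return Subclass(
        name="Psychological",
        class_label="psychological",
        descriptors=list(rules.psychological_selection),
    )


def reorder_subclass(
    descriptors: Sequence[str],
    intensities: Mapping[str, float],
    direction: str = "ascending",
):
    """Stable sort of descriptors by intensity; returns (ordered, changed).

    Ties preserve input order; ``changed`` is true iff the output order
    differs from the input. A descriptor with no intensity is an error.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be ascending|descending")
    missing = [d for d in descriptors if d not in intensities or intensities[d] is None]
    if missing:
        raise ValueError(f"missing intensity for descriptors: {missing}")
    sign = 1.0 if direction == "ascending" else -1.0
    ordered = sorted(descriptors, key=lambda d: sign * intensities[d])
    return ordered, ordered != list(descriptors)


def assemble_and_report(
    original: Questionnaire,
    survivors: Questionnaire,
    additions: Sequence[tuple],
    psychological: Subclass,
    intensities: Mapping[str, float],
    rules: RevisionRules,
    threshold: int,
    removals: Sequence[tuple],
):
    """Assemble the revised questionnaire and its report.

    Per subclass the surviving original descriptors are reordered by
    intensity (the ``reordered`` flag refers to this pre-existing-word
    order, matching the published comparison), then the subclass's
    additions are merged in at their intensity position via a second
    stable sort. Emptied subclasses are dropped; the psychological
    subclass is appended.
    """
    known = {sc.name for sc in original.subclasses}
    by_subclass: dict[str, list] = {}
    placed = set()
    for word, subclass in additions:
        if subclass not in known:
            raise ValueError(f"addition {word!r} assigned to unknown subclass {subclass!r}")
        if word in placed or word in survivors.all_descriptors():
            raise ValueError(f"duplicate descriptor across subclasses: {word!r}")
        placed.add(word)
        by_subclass.setdefault(subclass, []).append(word)

    revised_subclasses = []
    reordered_names = []
    diffs = {}
    for orig_sc in original.subclasses:
        surv = survivors.subclass(orig_sc.name).descriptors
        ordered, changed = reorder_subclass(surv, intensities, rules.reorder_direction)
        merged = ordered + by_subclass.get(orig_sc.name, [])
        merged, _ = reorder_subclass(merged, intensities, rules.reorder_direction)
        if changed:
            reordered_names.append(orig_sc.name)
        diffs[orig_sc.name] = {
            "removed": [d for d in orig_sc.descriptors if d not in surv],
            "added": by_subclass.get(orig_sc.name, []),
            "reordered": changed,
        }
        if merged:
            revised_subclasses.append(
                Subclass(name=orig_sc.name, class_label=orig_sc.class_label, descriptors=merged)
            )
    new_subclasses = []
    if psychological.descriptors:
        revised_subclasses.append(psychological)
        new_subclasses.append(psychological.name)
    revised = Questionnaire(subclasses=revised_subclasses)
    report = RevisionReport(
        threshold_used=threshold,
        removed=list(removals),
        added=list(additions),
        new_subclasses=new_subclasses,
        reordered_subclasses=reordered_names,
        per_subclass_diffs=diffs,
    )
    return revised, report


def revise_questionnaire(
    original: Questionnaire,
    original_counts: Mapping[str, int],
    new_word_stats: Mapping[str, "object"],
    psychological_stats: Mapping[str, "object"],
    intensities: Mapping[str, float],
    rules: RevisionRules,
):
    """Run the full revision chain; returns (revised, report)."""
    threshold, _bottom = derive_threshold(original_counts, rules.decile)
    removals, survivors = apply_removal_rules(original, original_counts, threshold, rules)
    additions = apply_addition_rules(new_word_stats, threshold, rules)
    psychological = build_psychological_subclass(psychological_stats, rules)
    return assemble_and_report(
        original, survivors, additions, psychological, intensities, rules, threshold, removals
    )
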