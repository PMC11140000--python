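"""Vocabulary-based functional classification.

Each CDS is assigned one of an ordered set of functional classes by
scanning its ranked homology-hit descriptions against an ordered keyword
vocabulary (case-insensitive, whole-word, phrases allowed). The first
keyword-bearing description decides; within it the keyword with the
smallest character offset wins, ties broken by vocabulary order (class
order, then keyword order within the class). A CDS with hits but no
keyword match is "unknown conserved" (similar to deposited sequences of
unknown function — typically "hypothetical protein" entries); a CDS with
no hits at all is "unknown".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

UNKNOWN = "unknown"
UNKNOWN_CONSERVED = "unknown conserved"
RULE_CLASSES = (UNKNOWN_CONSERVED, UNKNOWN)

DEFAULT_UNINFORMATIVE = ("hypothetical", "uncharacterized", "unknown",
                         "unnamed", "predicted protein")


@dataclass(frozen=True)
class Classification:
    cds_id: str
    class_label: str
    matched_keyword: str | None = None
    source_subject: str | None = None
    source_db_rank: int | None = None

    def __post_init__(self):
        if (self.matched_keyword is None) != (self.class_label in RULE_CLASSES):
            raise ValueError(
                "matched_keyword must be absent exactly for the rule-assigned classes"
            )


@dataclass
class Vocabulary:
    classes: list  # ordered class labels, including the two rule classes
    keywords: dict  # class label -> ordered keyword list
    uninformative_terms: tuple = DEFAULT_UNINFORMATIVE
    _patterns: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class labels")
        seen = {}
        for label in self.classes:
            for kw in self.keywords.get(label, []):
                key = kw.lower()
                if key in seen:
                    raise ValueError(
                        f"keyword {kw!r} appears in classes "
                        f"{seen[key]!r} and {label!r}"
                    )
                seen[key] = label
        for label in RULE_CLASSES:
            if label in self.classes and self.keywords.get(label):
                raise ValueError(f"{label!r} must have an empty keyword list")
        self._patterns = []
        for ci, label in enumerate(self.classes):
            for ki, kw in enumerate(self.keywords.get(label, [])):
                pattern = re.compile(
                    r"(?<!\w)" + re.escape(kw.lower()) + r"(?!\w)"
                )
                self._patterns.append((pattern, label, kw, ci, ki))

    @property
    def n_keywords(self) -> int:
        return sum(len(v) for v in self.keywords.values())

    def match(self, description: str):
        """Best keyword match in one description, or ``None``.

        Returns ``(offset, class_order, keyword_order, class_label, keyword)``
        minimising (offset, class order, keyword order).
        """
        text = description.lower()
        best = None
        for pattern, label, kw, ci, ki in self._patterns:
            m = pattern.search(text)
            if m is None:
                continue
            key = (m.start(), ci, ki)
            if best is None or key < best[0]:
                best = (key, label, kw)
        if best is None:
            return None
        (offset, ci, ki), label, kw = best
        return offset, ci, ki, label, kw

    def to_file(self, path: str | Path) -> None:
        lines = ["# class label: comma-separated keywords (ordered; may be empty)"]
        for label in self.classes:
            lines.append(f"{label}: {', '.join(self.keywords.get(label, []))}")
        Path(path).write_text("\n".join(lines) + "\n")


def load_vocabulary(path: str | Path) -> Vocabulary:
    classes = []
    keywords = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}, line {lineno}: expected 'class: keywords'")
        label, _, rest = line.partition(":")
        label = label.strip()
        if label in keywords:
            raise ValueError(f"{path}, line {lineno}: duplicate class {label!r}")
        classes.append(label)
        keywords[label] = [k.strip() for k in rest.split(",") if k.strip()]
    return Vocabulary(classes, keywords)


def default_vocabulary() -> Vocabulary:
    with resources.as_file(
        resources.files("ticktx.data").joinpath("vocabulary.txt")
    ) as path:
        return load_vocabulary(path)


def classify_cds(cds_id: str, ranked_hits, vocabulary: Vocabulary) -> Classification:
    """Assign one functional class from ranked homology hits."""
    if not ranked_hits:
        return Classification(cds_id, UNKNOWN)
    for hit in ranked_hits:
        found = vocabulary.match(hit.subject_description)
        if found is not None:
            _, _, _, label, kw = found
            return Classification(cds_id, label, kw, hit.subject_id, hit.db_rank)
    return Classification(cds_id, UNKNOWN_CONSERVED)


def classify_all(records, hits_by_orf, vocabulary: Vocabulary) -> dict:
    """Classification per CDS record; contaminant-flagged records excluded."""
    out = {}
    for rec in records:
        if rec.contaminant:
            continue
        hits = hits_by_orf.get(rec.orf_id, [])
        out[rec.cds_id] = classify_cds(rec.cds_id, hits, vocabulary)
    return out
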