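"""Concept extraction: free text + diagnosis codes -> binary record matrix.

Emergency-department records carry four free-text fields (chief complaint,
triage assessment, nursing notes, MD comments) and structured diagnosis
codes.  Extraction is deliberately rudimentary string matching:

1. negation scopes are found with a small trigger/terminator rule set in the
   NegEx family (a fixed 6-token forward scope);
2. concept aliases are matched case-insensitively at word boundaries, longest
   alias first, non-overlapping;
3. a record is positive for a concept if it has at least one non-negated
   mention or lists a diagnosis code mapped to that concept.

Concepts without enough support are dropped afterwards: diseases need at
least 100 positive mentions and symptoms at least 10 by default.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .matrix import ROLE_DISEASE, ROLE_SYMPTOM, RecordMatrix
from .vocabulary import ConceptVocabulary

logger = logging.getLogger(__name__)

TEXT_FIELDS = ("chief_complaint", "triage_assessment", "nursing_notes", "md_comments")
AGE_BRACKETS = ("child", "young adult", "adult", "senior")
UNKNOWN_BRACKET = "unknown"

DEFAULT_NEGATION_TRIGGERS: tuple[str, ...] = (
    "denies",
    "denied",
    "no",
    "not",
    "without",
    "negative for",
    "free of",
    "ruled out",
)
#: words that close a negation scope
TERMINATION_TOKENS = frozenset({"but", "however", "except"})
#: punctuation that closes a negation scope (sentence ends and clause breaks)
TERMINATION_PUNCT = frozenset(".,;:!?")
#: maximum forward extent of a scope, in tokens
SCOPE_TOKENS = 6

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")

DEFAULT_MIN_DISEASE_SUPPORT = 100
DEFAULT_MIN_SYMPTOM_SUPPORT = 10


@dataclass
class TextRecord:
    """A single patient visit: free-text fields plus structured codes."""

    record_id: str
    age_bracket: str = UNKNOWN_BRACKET
    fields: dict[str, str] = field(default_factory=dict)
    codes: list[str] = field(default_factory=list)

    def text(self, field_name: str) -> str:
        return self.fields.get(field_name, "")


@dataclass(frozen=True)
class Mention:
    """An alias match inside one text field, with its negation status."""

    concept_id: str
    field_name: str
    start: int
    end: int
    negated: bool


def _tokens(text: str) -> list[tuple[str, int, int]]:
    return [(m.group().lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def detect_negation_scopes(
    text: str, triggers: Sequence[str] = DEFAULT_NEGATION_TRIGGERS
) -> list[tuple[int, int]]:
    """Half-open character intervals covered by negation.

    Each trigger occurrence opens a scope from the token after the trigger to
    the earliest of a termination token ('but', 'however', 'except'),
    clause/sentence punctuation, or 6 tokens.  Overlapping scopes are merged.
    """
    if not text or not triggers:
        return []
    toks = _tokens(text)
    trigger_seqs = sorted(
        (tuple(t.lower().split()) for t in triggers), key=len, reverse=True
    )
    raw: list[tuple[int, int]] = []
    i = 0
    while i < len(toks):
        matched = None
        for seq in trigger_seqs:
            if i + len(seq) <= len(toks) and all(
                toks[i + k][0] == seq[k] for k in range(len(seq))
            ):
                matched = seq
                break
        if matched is None:
            i += 1
            continue
        first = i + len(matched)
        end_tok = first
        for k in range(first, min(first + SCOPE_TOKENS, len(toks))):
            if toks[k][0] in TERMINATION_TOKENS:
                break
            # punctuation between the previous token and this one closes scope
            gap_start = toks[k - 1][2] if k > first else toks[i + len(matched) - 1][2]
            gap = text[gap_start : toks[k][1]]
            if any(ch in TERMINATION_PUNCT for ch in gap):
                break
            end_tok = k + 1
        if end_tok > first:
            raw.append((toks[first][1], toks[end_tok - 1][2]))
        i += 1
    raw.sort()
    merged: list[tuple[int, int]] = []
    for start, end in raw:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _alias_pattern(alias: str) -> re.Pattern:
    # word-boundary match that tolerates flexible internal whitespace
    parts = [re.escape(p) for p in alias.split()]
    body = r"\s+".join(parts)
    return re.compile(rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])", re.IGNORECASE)


class _AliasMatcher:
    """Precompiled longest-first alias matcher for one vocabulary."""

    def __init__(self, vocabulary: ConceptVocabulary):
        amap = vocabulary.alias_map
        self.entries = sorted(
            ((alias, _alias_pattern(alias), cid) for alias, cid in amap.items()),
            key=lambda e: (-len(e[0]), e[0]),
        )

    def matches(self, text: str) -> list[tuple[int, int, str]]:
        """Non-overlapping (start, end, concept_id); longer alias wins, then leftmost."""
        taken: list[tuple[int, int]] = []
        out: list[tuple[int, int, str]] = []
        for _alias, pat, cid in self.entries:
            for m in pat.finditer(text):
                s, e = m.start(), m.end()
                if any(s < te and ts < e for ts, te in taken):
                    continue
                taken.append((s, e))
                out.append((s, e, cid))
        out.sort()
        return out


def find_mentions(
    record: TextRecord,
    vocabulary: ConceptVocabulary,
    triggers: Sequence[str] = DEFAULT_NEGATION_TRIGGERS,
    matcher: "_AliasMatcher | None" = None,
) -> list[Mention]:
    """All alias matches across the record's text fields with negation flags."""
    matcher = matcher or _AliasMatcher(vocabulary)
    mentions: list[Mention] = []
    for field_name in TEXT_FIELDS:
        text = record.text(field_name)
        if not text:
            continue
        scopes = detect_negation_scopes(text, triggers)
        for s, e, cid in matcher.matches(text):
            negated = any(s < scope_end and scope_start < e for scope_start, scope_end in scopes)
            mentions.append(Mention(cid, field_name, s, e, negated))
    return mentions


def build_record_matrix(
    records: Iterable[TextRecord],
    vocabulary: ConceptVocabulary,
    triggers: Sequence[str] = DEFAULT_NEGATION_TRIGGERS,
) -> RecordMatrix:
    """Binary matrix: cell = 1 iff a non-negated mention or a mapped code.

    Column order follows the vocabulary; duplicate record ids are an error.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    ids = [r.record_id for r in records]
    dupes = [rid for rid, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate record ids: {dupes[:5]}")
    concepts = [c.concept_id for c in vocabulary.concepts]
    roles = [c.role for c in vocabulary.concepts]
    col = {cid: i for i, cid in enumerate(concepts)}
    code_map = vocabulary.code_map()
    matcher = _AliasMatcher(vocabulary)
    cells = np.zeros((len(records), len(concepts)), dtype=np.int8)
    for row, record in enumerate(records):
        for mention in find_mentions(record, vocabulary, triggers, matcher=matcher):
            if not mention.negated:
                cells[row, col[mention.concept_id]] = 1
        for code in record.codes:
            for cid in code_map.get(code, ()):
                cells[row, col[cid]] = 1
    return RecordMatrix(
        patients=ids,
        concepts=concepts,
        roles=roles,
        cells=cells,
        age_brackets=[r.age_bracket for r in records],
    )


def apply_support_filter(
    matrix: RecordMatrix,
    min_disease: int = DEFAULT_MIN_DISEASE_SUPPORT,
    min_symptom: int = DEFAULT_MIN_SYMPTOM_SUPPORT,
) -> RecordMatrix:
    """Drop concept columns with insufficient positive mentions.

    Disease columns need at least ``min_disease`` positives and symptom
    columns at least ``min_symptom``; patients are retained even if their row
    becomes all-zero.  Idempotent.
    """
    if min_disease < 0 or min_symptom < 0:
        raise ValueError("support thresholds must be nonnegative")
    marg = matrix.marginals()
    roles = np.asarray(matrix.roles)
    thresholds = np.where(roles == ROLE_DISEASE, min_disease, min_symptom)
    keep = np.flatnonzero(marg >= thresholds)
    dropped = len(matrix.concepts) - len(keep)
    if len(matrix.concepts):
        logger.info(
            "support filter dropped %d/%d concepts (%.1f%%)",
            dropped,
            len(matrix.concepts),
            100.0 * dropped / len(matrix.concepts),
        )
    return matrix.subset_concepts(keep)


def summarize_counts(matrix: RecordMatrix) -> dict[str, dict[str, dict[int, int]]]:
    """Per-age-bracket histograms of diseases and symptoms per record."""
    out: dict[str, dict[str, dict[int, int]]] = {}
    d_counts = matrix.disease_block().sum(axis=1)
    s_counts = matrix.symptom_block().sum(axis=1)
    for bracket in sorted(set(matrix.age_brackets)):
        rows = [i for i, b in enumerate(matrix.age_brackets) if b == bracket]
        out[bracket] = {
            "diseases": dict(Counter(int(d_counts[i]) for i in rows)),
            "symptoms": dict(Counter(int(s_counts[i]) for i in rows)),
        }
    return out


# -- record serialization --------------------------------------------------


def write_records_jsonl(records: Iterable[TextRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "record_id": r.record_id,
                        "age_bracket": r.age_bracket,
                        "fields": r.fields,
                        "codes": r.codes,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def load_records_jsonl(path: str | Path) -> list[TextRecord]:
    records = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            records.append(
                TextRecord(
                    record_id=doc["record_id"],
                    age_bracket=doc.get("age_bracket", UNKNOWN_BRACKET),
                    fields=doc.get("fields", {}),
                    codes=list(doc.get("codes", [])),
                )
            )
    return records
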