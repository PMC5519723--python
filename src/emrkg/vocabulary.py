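"""Concept vocabularies, reference graphs and edge-list serialization.

The vocabulary is the node set of every graph: diseases and symptoms with
display names, aliases/acronyms used for string matching, and optional
diagnosis-code mappings.  A curated *reference graph* (in the style of a
manually maintained health knowledge graph) supplies the edges used as the
automatic evaluation target, with per-edge frequency buckets ('frequent' or
'always') and per-disease, per-age-bracket expected frequency labels.

File formats (all UTF-8, LF):

* vocabulary: TSV with columns ``concept_id, name, role, aliases, codes``
  (aliases pipe-separated, codes comma-separated, both optional);
* reference graph: JSON ``{"edges": [...], "disease_frequency": {...}}``;
* edge lists: TSV ``disease_id, symptom_id, importance`` at 6 decimals,
  sorted by disease then descending importance (ties by symptom id).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .graph import KnowledgeGraph, edge_sort_key

logger = logging.getLogger(__name__)

ROLE_DISEASE = "disease"
ROLE_SYMPTOM = "symptom"
ROLES = (ROLE_DISEASE, ROLE_SYMPTOM)

FREQUENCY_BUCKETS = ("frequent", "always")
DISEASE_FREQUENCY_LEVELS = ("very frequent", "frequent", "rare", "very rare", "never")

VOCAB_COLUMNS = ["concept_id", "name", "role", "aliases", "codes"]


class VocabularyError(ValueError):
    """Raised on malformed vocabulary or reference-graph inputs."""


@dataclass(frozen=True)
class Concept:
    concept_id: str
    name: str
    role: str
    aliases: tuple[str, ...] = ()
    codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise VocabularyError(
                f"unknown role {self.role!r} for concept {self.concept_id!r}"
            )

    @property
    def effective_aliases(self) -> tuple[str, ...]:
        """Aliases including the display name itself, case-deduplicated."""
        seen: dict[str, str] = {}
        for alias in (self.name, *self.aliases):
            key = alias.lower().strip()
            if key and key not in seen:
                seen[key] = alias
        return tuple(seen.values())


class ConceptVocabulary:
    """Validated collection of concepts with a deterministic alias map.

    Alias collisions (one alias string claimed by several concepts) are
    resolved by preferring the disease-role concept, then the
    lexicographically smallest concept id; each resolution is logged.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self._concepts:
                raise VocabularyError(f"duplicate concept_id {c.concept_id!r}")
            self._concepts[c.concept_id] = c
        self._alias_map: dict[str, str] = {}
        claims: dict[str, list[Concept]] = {}
        for c in self._concepts.values():
            for alias in c.effective_aliases:
                claims.setdefault(alias.lower(), []).append(c)
        for alias, claimants in claims.items():
            if len(claimants) > 1:
                claimants.sort(key=lambda c: (c.role != ROLE_DISEASE, c.concept_id))
                logger.info(
                    "alias %r claimed by %s; resolved to %s",
                    alias,
                    [c.concept_id for c in claimants],
                    claimants[0].concept_id,
                )
            self._alias_map[alias] = claimants[0].concept_id

    # -- access -----------------------------------------------------------

    @property
    def concepts(self) -> list[Concept]:
        return list(self._concepts.values())

    @property
    def alias_map(self) -> dict[str, str]:
        """Lowercased alias -> concept_id after collision resolution."""
        return dict(self._alias_map)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self._concepts[concept_id]

    def __len__(self) -> int:
        return len(self._concepts)

    def role(self, concept_id: str) -> str:
        return self._concepts[concept_id].role

    @property
    def diseases(self) -> list[Concept]:
        return [c for c in self._concepts.values() if c.role == ROLE_DISEASE]

    @property
    def symptoms(self) -> list[Concept]:
        return [c for c in self._concepts.values() if c.role == ROLE_SYMPTOM]

    @property
    def counts(self) -> tuple[int, int]:
        """(number of diseases, number of symptoms)."""
        return len(self.diseases), len(self.symptoms)

    def code_map(self) -> dict[str, list[str]]:
        """Diagnosis code -> concept ids listing it."""
        out: dict[str, list[str]] = {}
        for c in self._concepts.values():
            for code in c.codes:
                out.setdefault(code, []).append(c.concept_id)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConceptVocabulary):
            return NotImplemented
        return self._concepts == other._concepts


def resolve_role_conflicts(raw_concepts: Iterable[Concept]) -> ConceptVocabulary:
    """Collapse concepts listed under both roles to a single disease entry.

    Concepts are grouped by (case-insensitive) display name; if any member of
    a group carries the disease role, the group is emitted once as a disease
    (aliases and codes unioned) and each demotion is logged.  Applying the
    resolution twice is a no-op.
    """
    groups: dict[str, list[Concept]] = {}
    order: list[str] = []
    for c in raw_concepts:
        key = c.name.lower()
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(c)
    resolved: list[Concept] = []
    for key in order:
        members = sorted(groups[key], key=lambda c: (c.role != ROLE_DISEASE, c.concept_id))
        primary = members[0]
        if len(members) == 1:
            resolved.append(primary)
            continue
        roles = {c.role for c in members}
        if len(roles) > 1:
            logger.info(
                "concept %r listed as both disease and symptom; kept as disease %s",
                primary.name,
                primary.concept_id,
            )
        aliases: list[str] = []
        codes: list[str] = []
        for c in members:
            aliases.extend(a for a in c.aliases if a not in aliases)
            codes.extend(code for code in c.codes if code not in codes)
        resolved.append(
            replace(primary, aliases=tuple(aliases), codes=tuple(codes))
        )
    return ConceptVocabulary(resolved)


def load_vocabulary(path: str | Path) -> ConceptVocabulary:
    """Load a TSV vocabulary, resolving dual-role concepts to diseases."""
    path = Path(path)
    raw: list[Concept] = []
    seen_ids: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in VOCAB_COLUMNS[:3] if c not in (reader.fieldnames or [])]
        if missing:
            raise VocabularyError(f"vocabulary missing columns {missing} in {path}")
        for lineno, row in enumerate(reader, start=2):
            cid = (row.get("concept_id") or "").strip()
            role = (row.get("role") or "").strip().lower()
            if role not in ROLES:
                raise VocabularyError(f"unknown role {role!r} at line {lineno}")
            if cid in seen_ids:
                raise VocabularyError(f"duplicate concept_id {cid!r}")
            seen_ids.add(cid)
            aliases = tuple(
                a.strip() for a in (row.get("aliases") or "").split("|") if a.strip()
            )
            codes = tuple(
                c.strip() for c in (row.get("codes") or "").split(",") if c.strip()
            )
            raw.append(
                Concept(
                    concept_id=cid,
                    name=(row.get("name") or "").strip(),
                    role=role,
                    aliases=aliases,
                    codes=codes,
                )
            )
    return resolve_role_conflicts(raw)


def write_vocabulary(vocabulary: ConceptVocabulary, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VOCAB_COLUMNS)
        for c in vocabulary.concepts:
            writer.writerow(
                [c.concept_id, c.name, c.role, "|".join(c.aliases), ",".join(c.codes)]
            )


# -- reference graph -------------------------------------------------------


@dataclass(frozen=True)
class ReferenceEdge:
    disease_id: str
    symptom_id: str
    frequency_bucket: str

    def __post_init__(self) -> None:
        if self.frequency_bucket not in FREQUENCY_BUCKETS:
            raise VocabularyError(
                f"unknown frequency bucket {self.frequency_bucket!r}"
            )


@dataclass
class ReferenceGraph:
    """Curated evaluation target: bucketed edges plus disease frequencies."""

    edges: set[ReferenceEdge]
    disease_frequency: dict[str, dict[str, str]] = field(default_factory=dict)
    skipped: int = 0

    def __post_init__(self) -> None:
        pairs = {(e.disease_id, e.symptom_id) for e in self.edges}
        if len(pairs) != len(self.edges):
            raise VocabularyError("duplicate reference edges")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(e.disease_id, e.symptom_id) for e in self.edges}

    def has_edge(self, disease_id: str, symptom_id: str) -> bool:
        return (disease_id, symptom_id) in self.pairs

    def bucket_scores(self) -> dict[tuple[str, str], float]:
        """Buckets as a two-level score (always=2, frequent=1) for PR points."""
        return {
            (e.disease_id, e.symptom_id): 2.0 if e.frequency_bucket == "always" else 1.0
            for e in self.edges
        }


def load_reference_graph(
    path: str | Path, vocabulary: ConceptVocabulary
) -> ReferenceGraph:
    """Load a reference graph, skipping (and counting) unresolvable ids."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise VocabularyError(f"malformed reference graph JSON {path}: {exc}") from exc
    edges: set[ReferenceEdge] = set()
    skipped = 0
    for entry in doc.get("edges", []):
        d, s = entry.get("disease"), entry.get("symptom")
        if (
            d not in vocabulary
            or s not in vocabulary
            or vocabulary.role(d) != ROLE_DISEASE
            or vocabulary.role(s) != ROLE_SYMPTOM
        ):
            skipped += 1
            logger.warning("skipping reference edge with unresolved ids (%s, %s)", d, s)
            continue
        edges.add(ReferenceEdge(d, s, entry.get("bucket", "frequent")))
    freq = {}
    for d, table in doc.get("disease_frequency", {}).items():
        if d in vocabulary:
            freq[d] = dict(table)
        else:
            skipped += 1
    return ReferenceGraph(edges=edges, disease_frequency=freq, skipped=skipped)


def write_reference_graph(graph: ReferenceGraph, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "edges": [
            {"disease": e.disease_id, "symptom": e.symptom_id, "bucket": e.frequency_bucket}
            for e in sorted(graph.edges, key=lambda e: (e.disease_id, e.symptom_id))
        ],
        "disease_frequency": graph.disease_frequency,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")


# -- edge lists ------------------------------------------------------------


def write_edge_list(graph: KnowledgeGraph, path: str | Path) -> None:
    """Serialize a scored graph as TSV, importance at 6 decimal places."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    for d, s, v in graph.edges:
        if not math.isfinite(v):
            raise ValueError(f"non-finite importance for edge ({d}, {s})")
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease_id", "symptom_id", "importance"])
        for d, s, v in sorted(graph.edges, key=edge_sort_key):
            writer.writerow([d, s, f"{v:.6f}"])


def read_edge_list(path: str | Path) -> KnowledgeGraph:
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            edges.append(
                (row["disease_id"], row["symptom_id"], float(row["importance"]))
            )
    return KnowledgeGraph(edges=edges, provenance={"source": str(path)})
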