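"""Scored disease -> symptom knowledge graphs and the importance measures.

Each fitted model is translated into per-pair *importance* scores expressing
the model's confidence that an edge exists:

* logistic regression: ``IMPT_LR = max(b_ij, 0)`` — only symptoms whose
  presence raises the disease probability suggest edges;
* naive Bayes: ``IMPT_NB = log p(x_i=1|y_j=1) - log p(x_i=1|y_j=0)`` — the
  log relative risk, so a rare symptom made three times more likely scores the
  same as a common one made three times more likely;
* noisy OR: ``IMPT = 1 - f_ij`` — one minus the fitted failure probability,
  the probability that a present disease turns the symptom on beyond the leak.

Scores are turned into a graph either by thresholding or by keeping the top-N
symptoms per disease, after an optional co-occurrence de-noising floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: model kinds the co-occurrence floor applies to
COOCCURRENCE_FILTERED_MODELS = frozenset({"naive_bayes", "logistic"})


def edge_sort_key(edge: tuple[str, str, float]):
    """Total order on edges: disease asc, importance desc, symptom asc."""
    disease, symptom, score = edge
    return (disease, -score, symptom)


@dataclass
class KnowledgeGraph:
    """A set of scored directed disease -> symptom edges."""

    edges: list[tuple[str, str, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(d, s) for d, s, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (disease, symptom) pairs in graph")
        self.edges = sorted(self.edges, key=edge_sort_key)

    @property
    def pair_scores(self) -> dict[tuple[str, str], float]:
        return {(d, s): v for d, s, v in self.edges}

    @property
    def diseases(self) -> list[str]:
        return sorted({d for d, _, _ in self.edges})

    def edges_for(self, disease_id: str) -> list[tuple[str, float]]:
        """Symptoms of one disease, sorted by descending importance."""
        return [(s, v) for d, s, v in self.edges if d == disease_id]

    def top_n(self, n: int) -> "KnowledgeGraph":
        return build_graph(self.pair_scores, top_n=n, provenance=dict(self.provenance))

    def to_networkx(self):
        """Directed bipartite graph with importance as edge weight."""
        import networkx as nx

        g = nx.DiGraph()
        for d, s, v in self.edges:
            g.add_node(d, role="disease")
            g.add_node(s, role="symptom")
            g.add_edge(d, s, importance=v)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        if len(self.edges) != len(other.edges):
            return False
        return all(
            a[0] == b[0] and a[1] == b[1] and np.isclose(a[2], b[2], atol=1e-9)
            for a, b in zip(self.edges, other.edges)
        )


# -- importance measures --------------------------------------------------


def importance_lr(model) -> dict[str, float]:
    """Per-symptom score max(b_ij, 0) from a fitted :class:`LogisticModel`."""
    return {
        sid: float(max(w, 0.0)) for sid, w in zip(model.symptom_ids, model.weights)
    }


def importance_nb(model) -> dict[str, float]:
    """Per-symptom log relative risk from a fitted :class:`NaiveBayesModel`."""
    scores = np.log(model.p_present) - np.log(model.p_absent)
    return {sid: float(v) for sid, v in zip(model.symptom_ids, scores)}


def importance_noisy_or(model) -> dict[tuple[str, str], float]:
    """Per-(disease, symptom) score 1 - f_ij from a fitted :class:`NoisyOrModel`."""
    out: dict[tuple[str, str], float] = {}
    for i, sid in enumerate(model.symptom_ids):
        for j, did in enumerate(model.disease_ids):
            out[(did, sid)] = float(1.0 - model.failure[i, j])
    return out


def as_pair_scores(disease_id: str, symptom_scores: Mapping[str, float]):
    """Lift a per-symptom score map (one disease's model) to pair keys."""
    return {(disease_id, sid): float(v) for sid, v in symptom_scores.items()}


# -- filters and graph construction ---------------------------------------


def cooccurrence_filter(
    scores: Mapping[tuple[str, str], float],
    matrix,
    min_count: int = 5,
    applies_to: str = "naive_bayes",
    force: bool = False,
) -> dict[tuple[str, str], float]:
    """De-noising floor: drop pairs with fewer than ``min_count`` co-occurrences.

    The floor applies to the pairwise models (naive Bayes, logistic
    regression); noisy-OR scores pass through unchanged unless ``force`` is
    set.  Filtered pairs are removed outright rather than zeroed, so a later
    threshold of 0 cannot resurrect them.
    """
    if applies_to not in COOCCURRENCE_FILTERED_MODELS and not force:
        return dict(scores)
    counts = matrix.cooccurrence_counts()
    d_index = {d: j for j, d in enumerate(matrix.disease_ids)}
    s_index = {s: i for i, s in enumerate(matrix.symptom_ids)}
    kept: dict[tuple[str, str], float] = {}
    for (d, s), v in scores.items():
        if counts[d_index[d], s_index[s]] >= min_count:
            kept[(d, s)] = v
    return kept


def build_graph(
    scores: Mapping[tuple[str, str], float],
    threshold: float | None = None,
    top_n: int | None = None,
    provenance: dict | None = None,
) -> KnowledgeGraph:
    """Select edges from pair scores by threshold or per-disease top-N.

    Exactly one of ``threshold`` / ``top_n`` must be given.  Threshold mode
    keeps pairs with score >= threshold; top-N mode keeps, per disease, the N
    highest-scoring symptoms with ties broken by symptom id.
    """
    if (threshold is None) == (top_n is None):
        raise ValueError("specify exactly one of threshold or top_n")
    for (d, s), v in scores.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite score for edge ({d}, {s})")
    provenance = dict(provenance or {})
    if threshold is not None:
        provenance["mode"] = {"threshold": threshold}
        edges = [(d, s, float(v)) for (d, s), v in scores.items() if v >= threshold]
        return KnowledgeGraph(edges=edges, provenance=provenance)
    if top_n < 0:
        raise ValueError("top_n must be nonnegative")
    provenance["mode"] = {"top_n": top_n}
    per_disease: dict[str, list[tuple[str, float]]] = {}
    for (d, s), v in scores.items():
        per_disease.setdefault(d, []).append((s, float(v)))
    edges = []
    for d, items in per_disease.items():
        items.sort(key=lambda sv: (-sv[1], sv[0]))
        if top_n < len(items) and items:
            cut = items[top_n - 1][1] if top_n else None
            if top_n and items[top_n][1] == cut:
                logger.info("top-%d tie at score %.6f for disease %s", top_n, cut, d)
        edges.extend((d, s, v) for s, v in items[:top_n])
    return KnowledgeGraph(edges=edges, provenance=provenance)
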