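"""Evaluation of candidate knowledge graphs.

Two frameworks:

* **automatic** — binary-target precision/recall against a curated reference
  graph, sweeping every distinct importance score as a threshold
  (micro-averaged over all disease-symptom pairs); the overly general symptom
  'pain' is excluded by default;
* **clinical** — the pooling protocol: the top-N suggestions per disease from
  every model (plus the reference graph's edges) are unioned, shuffled so the
  rater is blinded to provenance, rated on the 4-point scale
  always/sometimes/rarely/never, binarized under one of two schemes, and
  scored with the same PR sweep.  Edges outside the pool count as irrelevant.

Comparison statistics: a Wilcoxon signed-rank test on paired per-disease
precisions (exact tie-corrected sign-flip null for up to 25 nonzero pairs)
and bootstrap Spearman rho for inter-rater agreement.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .graph import KnowledgeGraph
from .vocabulary import ReferenceGraph

logger = logging.getLogger(__name__)

TAG_SCALE = ("never", "rarely", "sometimes", "always")
TAG_ORDINAL = {t: i for i, t in enumerate(TAG_SCALE)}

SCHEME_RARELY_POSITIVE = "rarely_positive"
SCHEME_RARELY_NEGATIVE = "rarely_negative"

DEFAULT_EXCLUDED_SYMPTOMS = ("pain",)


@dataclass
class PRCurve:
    """Precision-recall points swept over importance thresholds."""

    points: list[tuple[float, float, float]]  # (threshold, precision, recall)
    label: str = ""

    def __post_init__(self) -> None:
        for t, p, r in self.points:
            if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
                raise ValueError(f"invalid PR point ({t}, {p}, {r})")

    def precision_at_recall(self, recall: float) -> float:
        """Best precision among points achieving at least the given recall."""
        cands = [p for _, p, r in self.points if r >= recall]
        if not cands:
            raise ValueError(f"no point reaches recall {recall}")
        return max(cands)

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["threshold", "precision", "recall"])
            for t, p, r in self.points:
                writer.writerow([f"{t:.6f}", f"{p:.6f}", f"{r:.6f}"])


def _sweep(
    scores: Mapping[tuple[str, str], float],
    positives: set[tuple[str, str]],
    denominator: int,
    label: str,
) -> PRCurve:
    """Micro-averaged PR over all distinct score thresholds (descending)."""
    items = sorted(scores.items(), key=lambda kv: -kv[1])
    points: list[tuple[float, float, float]] = []
    retrieved = 0
    tp = 0
    i = 0
    n = len(items)
    while i < n:
        t = items[i][1]
        while i < n and items[i][1] == t:
            retrieved += 1
            if items[i][0] in positives:
                tp += 1
            i += 1
        points.append((float(t), tp / retrieved, tp / denominator))
    return PRCurve(points=points, label=label)


def pr_vs_reference(
    graph_scores: Mapping[tuple[str, str], float],
    reference: ReferenceGraph,
    exclude_symptoms: Sequence[str] = DEFAULT_EXCLUDED_SYMPTOMS,
    restrict_to_scored: bool = True,
    label: str = "",
) -> PRCurve:
    """Binary-target PR against the reference edge set.

    Excluded symptoms are dropped from both candidate and reference sides.
    The recall denominator is the surviving reference edges; by default it is
    further restricted to edges whose concepts appear among the scored pairs
    (the supported vocabulary), ``restrict_to_scored=False`` uses all of them.
    """
    excluded = set(exclude_symptoms)
    scores = {
        (d, s): v for (d, s), v in graph_scores.items() if s not in excluded
    }
    ref_pairs = {p for p in reference.pairs if p[1] not in excluded}
    if restrict_to_scored:
        diseases = {d for d, _ in scores}
        symptoms = {s for _, s in scores}
        ref_pairs = {
            (d, s) for d, s in ref_pairs if d in diseases and s in symptoms
        }
    if not ref_pairs:
        raise ValueError("reference graph empty after exclusions")
    return _sweep(scores, ref_pairs, len(ref_pairs), label)


# -- pooling and physician tags -------------------------------------------


@dataclass
class PooledEdges:
    """Union of per-model top-N suggestions, in blinded shuffled order."""

    order: list[tuple[str, str]]
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.order)


def pool_top_edges(
    graphs: Sequence[KnowledgeGraph],
    n_per_disease: int,
    reference: ReferenceGraph | None = None,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> PooledEdges:
    """Pool each source's top-N-per-disease edges (plus reference edges).

    Duplicates are merged with provenance recorded; presentation order is
    shuffled deterministically by the seed so raters are blinded to source.
    """
    if labels is None:
        labels = [
            g.provenance.get("model", f"graph_{i}") for i, g in enumerate(graphs)
        ]
    provenance: dict[tuple[str, str], set[str]] = {}
    for g, lab in zip(graphs, labels):
        top = g.top_n(n_per_disease)
        for d, s, _ in top.edges:
            provenance.setdefault((d, s), set()).add(lab)
    if reference is not None:
        for pair in reference.pairs:
            provenance.setdefault(pair, set()).add("reference")
    order = sorted(provenance)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    return PooledEdges(order=[tuple(p) for p in order], provenance=provenance)


@dataclass
class PhysicianTags:
    """4-point ratings keyed by (disease_id, symptom_id, rater_id)."""

    ratings: dict[tuple[str, str, str], str]

    def __post_init__(self) -> None:
        for key, tag in self.ratings.items():
            if tag not in TAG_SCALE:
                raise ValueError(f"unknown tag {tag!r} for {key}")

    @property
    def raters(self) -> list[str]:
        return sorted({r for _, _, r in self.ratings})

    def for_rater(self, rater_id: str) -> dict[tuple[str, str], str]:
        return {
            (d, s): tag for (d, s, r), tag in self.ratings.items() if r == rater_id
        }


def load_physician_tags(path: str | Path) -> PhysicianTags:
    """CSV with header disease_id, symptom_id, rater_id, tag."""
    ratings: dict[tuple[str, str, str], str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["disease_id"], row["symptom_id"], row["rater_id"])
            if key in ratings:
                raise ValueError(f"duplicate rating for {key}")
            ratings[key] = row["tag"].strip().lower()
    return PhysicianTags(ratings=ratings)


def binarize_tags(
    tags: PhysicianTags, scheme: str = SCHEME_RARELY_POSITIVE
) -> dict[tuple[str, str, str], int]:
    """Binarize the 4-point scale.

    ``rarely_positive`` groups always/sometimes/rarely as positive (never is
    negative); ``rarely_negative`` is the alternative segmentation assigning
    both rarely and never to the negative category.
    """
    if scheme == SCHEME_RARELY_POSITIVE:
        positive = {"always", "sometimes", "rarely"}
    elif scheme == SCHEME_RARELY_NEGATIVE:
        positive = {"always", "sometimes"}
    else:
        raise ValueError(f"unknown binarization scheme {scheme!r}")
    return {key: int(tag in positive) for key, tag in tags.ratings.items()}


def pr_vs_tags(
    graph_scores: Mapping[tuple[str, str], float],
    relevance: Mapping[tuple[str, str], int],
    label: str = "",
) -> PRCurve:
    """PR sweep with binarized physician judgments as the target.

    ``relevance`` maps pooled (disease, symptom) pairs to 0/1; scored pairs
    outside the pool are counted as irrelevant.
    """
    positives = {pair for pair, rel in relevance.items() if rel}
    if not positives:
        raise ValueError("no positively tagged edges in the pool")
    return _sweep(dict(graph_scores), positives, len(positives), label)


def per_disease_precision(
    graph: KnowledgeGraph,
    positives: set[tuple[str, str]],
    n_per_disease: int,
) -> dict[str, float]:
    """Precision of each disease's top-N suggestions against a positive set.

    This is the paired quantity fed to :func:`wilcoxon_compare` when
    comparing two models at a matched edge budget.
    """
    top = graph.top_n(n_per_disease)
    out: dict[str, float] = {}
    for d in top.diseases:
        edges = top.edges_for(d)
        if edges:
            out[d] = sum((d, s) in positives for s, _ in edges) / len(edges)
    return out


# -- comparison statistics -------------------------------------------------


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_used: int
    method: str


def _exact_signflip_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p under the exact sign-flip null with (tied) ranks.

    Ranks are doubled to integers; the null distribution of W+ is built by
    dynamic-programming convolution, exact for up to ~50 pairs.
    """
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_compare(
    precision_a: Sequence[float],
    precision_b: Sequence[float],
    zero_method: str = "wilcox",
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired per-disease precisions.

    Zero differences are dropped (``zero_method='wilcox'``, the classic
    handling) or kept in the ranking and removed from the statistic
    (``'pratt'``).  Ties receive average ranks.  The null is the exact
    sign-flip distribution when at most ``exact_limit`` nonzero pairs remain,
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(precision_a, dtype=float)
    b = np.asarray(precision_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired observations")
    d = a - b
    if np.all(d == 0):
        raise ValueError("degenerate comparison: all paired differences are zero")
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks_all = stats.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = len(d)
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        p = _exact_signflip_pvalue(ranks, w_plus)
        method = "exact"
    else:
        mean = ranks.sum() / 2.0
        # sum of squared ranks / 4 is the tie-corrected null variance
        var = (ranks**2).sum() / 4.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(statistic=w_plus, pvalue=p, n_used=n, method=method)


@dataclass
class SpearmanAgreement:
    rho: float
    mean: float
    std: float
    ci_low: float
    ci_high: float
    n_replicates: int


def _as_ordinal(values: Sequence) -> np.ndarray:
    arr = list(values)
    if arr and isinstance(arr[0], str):
        try:
            arr = [TAG_ORDINAL[v] for v in arr]
        except KeyError as exc:
            raise ValueError(f"unknown tag token {exc.args[0]!r}") from exc
    return np.asarray(arr, dtype=float)


def spearman_agreement(
    ratings_a: Sequence,
    ratings_b: Sequence,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> SpearmanAgreement:
    """Inter-rater Spearman rho with a percentile bootstrap over edges.

    Ratings may be tag strings (ordered never < rarely < sometimes < always)
    or numbers.  Replicates whose resample is constant in either vector are
    skipped (rho undefined there).
    """
    a = _as_ordinal(ratings_a)
    b = _as_ordinal(ratings_b)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need two equal-length vectors of at least 3 ratings")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant rating vector: rho undefined")
    rho = float(stats.spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, len(a), len(a))
        ra, rb = a[idx], b[idx]
        if np.all(ra == ra[0]) or np.all(rb == rb[0]):
            continue
        reps.append(float(stats.spearmanr(ra, rb).statistic))
    reps_arr = np.asarray(reps)
    return SpearmanAgreement(
        rho=rho,
        mean=float(reps_arr.mean()),
        std=float(reps_arr.std(ddof=1)),
        ci_low=float(np.percentile(reps_arr, 2.5)),
        ci_high=float(np.percentile(reps_arr, 97.5)),
        n_replicates=len(reps),
    )
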