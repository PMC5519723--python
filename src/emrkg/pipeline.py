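"""End-to-end workflow: extract -> filter -> fit -> build graphs -> evaluate.

A run directory holds every artifact (matrix, fitted parameters, edge lists,
PR tables, comparison statistics) plus a manifest recording the config hash
and seeds, so re-running the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import evaluation, extraction, graph, models, vocabulary
from .matrix import RecordMatrix, save_matrix

logger = logging.getLogger(__name__)

MODEL_KINDS = ("noisy_or", "naive_bayes", "logistic")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    records_path: str
    vocabulary_path: str
    out_dir: str
    reference_path: str | None = None
    tags_path: str | None = None
    models: tuple[str, ...] = MODEL_KINDS
    min_disease: int = extraction.DEFAULT_MIN_DISEASE_SUPPORT
    min_symptom: int = extraction.DEFAULT_MIN_SYMPTOM_SUPPORT
    min_cooccurrence: int = 5
    top_n: int = 20
    exclude_symptoms: tuple[str, ...] = ()
    scheme: str = evaluation.SCHEME_RARELY_POSITIVE
    seed: int = 7

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_KINDS)
        if unknown:
            raise ValueError(f"unknown model kinds {sorted(unknown)}")
        for name in ("min_disease", "min_symptom", "min_cooccurrence", "top_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if "models" in doc:
            doc["models"] = tuple(doc["models"])
        if "exclude_symptoms" in doc:
            doc["exclude_symptoms"] = tuple(doc["exclude_symptoms"])
        return cls(**doc)


def _fit_model_scores(kind: str, matrix: RecordMatrix, seed: int):
    """Fit one model family and return its pair scores and parameter dump."""
    if kind == "noisy_or":
        model = models.fit_noisy_or(matrix, seed=seed)
        return graph.importance_noisy_or(model), [models.model_to_dict(model)]
    scores: dict[tuple[str, str], float] = {}
    dumps = []
    for disease in matrix.disease_ids:
        try:
            if kind == "naive_bayes":
                m = models.fit_naive_bayes(matrix, disease, seed=seed)
                per_symptom = graph.importance_nb(m)
            else:
                m = models.fit_logistic(matrix, disease, seed=seed)
                per_symptom = graph.importance_lr(m)
        except models.DegenerateLabelError:
            logger.warning("skipping %s for constant disease %s", kind, disease)
            continue
        scores.update(graph.as_pair_scores(disease, per_symptom))
        dumps.append(models.model_to_dict(m))
    return scores, dumps


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Any stage failure writes a FAILED marker naming the stage (partial
    outputs are retained) and re-raises as :class:`PipelineError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": [],
    }
    stage = "setup"

    def _artifact(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    try:
        stage = "load"
        vocab = vocabulary.load_vocabulary(config.vocabulary_path)
        records = extraction.load_records_jsonl(config.records_path)

        stage = "extract"
        matrix = extraction.build_record_matrix(records, vocab)
        matrix = extraction.apply_support_filter(
            matrix, config.min_disease, config.min_symptom
        )
        save_matrix(matrix, out / "matrix.mtx")
        _artifact(out / "matrix.mtx")

        reference = None
        if config.reference_path:
            reference = vocabulary.load_reference_graph(config.reference_path, vocab)

        graphs: dict[str, graph.KnowledgeGraph] = {}
        per_model_scores: dict[str, dict] = {}
        for kind in config.models:
            stage = f"fit:{kind}"
            scores, dumps = _fit_model_scores(kind, matrix, config.seed)
            params_path = out / f"params_{kind}.json"
            params_path.write_text(json.dumps(dumps, indent=1) + "\n", encoding="utf-8")
            _artifact(params_path)

            stage = f"build-graph:{kind}"
            scores = graph.cooccurrence_filter(
                scores, matrix, config.min_cooccurrence, applies_to=kind
            )
            per_model_scores[kind] = scores
            g = graph.build_graph(
                scores, top_n=config.top_n, provenance={"model": kind}
            )
            graphs[kind] = g
            graph_path = out / f"graph_{kind}.tsv"
            vocabulary.write_edge_list(g, graph_path)
            _artifact(graph_path)

        if reference is not None:
            stage = "evaluate:auto"
            positives: set[tuple[str, str]] = set()
            for kind, scores in per_model_scores.items():
                curve = evaluation.pr_vs_reference(
                    scores, reference, config.exclude_symptoms, label=kind
                )
                pr_path = out / f"pr_auto_{kind}.tsv"
                curve.write_tsv(pr_path)
                _artifact(pr_path)
                positives |= {
                    p for p in reference.pairs if p[1] not in set(config.exclude_symptoms)
                }
            stage = "compare"
            comparisons = {}
            kinds = list(graphs)
            for i in range(len(kinds)):
                for j in range(i + 1, len(kinds)):
                    a_prec = evaluation.per_disease_precision(
                        graphs[kinds[i]], positives, config.top_n
                    )
                    b_prec = evaluation.per_disease_precision(
                        graphs[kinds[j]], positives, config.top_n
                    )
                    shared = sorted(set(a_prec) & set(b_prec))
                    if len(shared) < 5:
                        continue
                    try:
                        res = evaluation.wilcoxon_compare(
                            [a_prec[d] for d in shared], [b_prec[d] for d in shared]
                        )
                    except ValueError as exc:
                        comparisons[f"{kinds[i]}_vs_{kinds[j]}"] = {"error": str(exc)}
                        continue
                    comparisons[f"{kinds[i]}_vs_{kinds[j]}"] = {
                        "statistic": res.statistic,
                        "pvalue": res.pvalue,
                        "n": res.n_used,
                        "method": res.method,
                    }
            cmp_path = out / "comparisons.json"
            cmp_path.write_text(
                json.dumps(comparisons, indent=1, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            _artifact(cmp_path)

        if config.tags_path:
            stage = "evaluate:clinical"
            tags = evaluation.load_physician_tags(config.tags_path)
            pool = evaluation.pool_top_edges(
                list(graphs.values()),
                config.top_n,
                reference=reference,
                seed=config.seed,
                labels=list(graphs),
            )
            binary = evaluation.binarize_tags(tags, config.scheme)
            for rater in tags.raters:
                relevance = {
                    (d, s): rel
                    for (d, s, r), rel in binary.items()
                    if r == rater and (d, s) in pool.pairs
                }
                if not any(relevance.values()):
                    logger.warning("no positive tags for rater %s; skipping", rater)
                    continue
                for kind, scores in per_model_scores.items():
                    pooled_scores = {
                        p: v for p, v in scores.items() if p in pool.pairs
                    }
                    curve = evaluation.pr_vs_tags(
                        pooled_scores, relevance, label=f"{kind}/{rater}"
                    )
                    pr_path = out / f"pr_clinical_{kind}_{rater}.tsv"
                    curve.write_tsv(pr_path)
                    _artifact(pr_path)
            raters = tags.raters
            if len(raters) >= 2:
                shared = sorted(
                    set(tags.for_rater(raters[0])) & set(tags.for_rater(raters[1]))
                )
                if len(shared) >= 3:
                    agreement = evaluation.spearman_agreement(
                        [tags.for_rater(raters[0])[p] for p in shared],
                        [tags.for_rater(raters[1])[p] for p in shared],
                        seed=config.seed,
                    )
                    agr_path = out / "inter_rater.json"
                    agr_path.write_text(
                        json.dumps(asdict(agreement), indent=1) + "\n",
                        encoding="utf-8",
                    )
                    _artifact(agr_path)
        else:
            logger.info("no physician tags supplied; clinical evaluation skipped")

        stage = "manifest"
        manifest["artifacts"].sort()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    except Exception as exc:  # noqa: BLE001 - report failing stage and re-raise
        (out / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        raise PipelineError(stage, exc) from exc
    return out
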