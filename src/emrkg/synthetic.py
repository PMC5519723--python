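"""Synthetic EMR generator with known disease-symptom ground truth.

Real emergency-department corpora cannot be shared, so every component is
exercised on generated data whose causal structure is known exactly.  The
generator emulates the salient statistical features of such corpora:

* an age bracket (child / young adult / adult / senior) acts as a shared
  latent cause: diseases are drawn independently *given* the bracket but are
  marginally correlated through it, which is precisely the confounding
  structure that trips up pairwise models;
* symptoms are drawn from the noisy-OR conditional
  ``P(x=1|y) = 1 - (1 - l_i) * prod_j f_ij**y_j`` given the sampled diseases,
  with optional bracket-driven direct activations (confounded symptoms with
  no causal edge);
* charting gaps are emulated by an omission probability applied to present
  symptoms (information missing not at random, in the simplest form);
* records can be rendered to free text through alias/negation templates, with
  diagnosis codes for mapped diseases, so the extraction pipeline can be
  tested end-to-end; with collision-free aliases and no omission the
  extracted matrix equals the generating one exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .extraction import AGE_BRACKETS, TEXT_FIELDS, TextRecord
from .graph import KnowledgeGraph
from .matrix import ROLE_DISEASE, ROLE_SYMPTOM, RecordMatrix
from .vocabulary import Concept, ConceptVocabulary

POSITIVE_TEMPLATES = (
    "presents with {}.",
    "reports {}.",
    "{} noted on exam.",
    "complains of {}.",
)
NEGATION_TEMPLATES = (
    "denies {}.",
    "no {}.",
    "negative for {}.",
)


@dataclass(frozen=True)
class SyntheticDisease:
    concept_id: str
    name: str
    prevalence: Mapping[str, float]  # per age bracket
    aliases: tuple[str, ...] = ()
    codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class SyntheticSymptom:
    concept_id: str
    name: str
    leak: float
    aliases: tuple[str, ...] = ()


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic corpus.

    ``true_graph`` maps (disease_id, symptom_id) to the failure probability
    f_ij; absent pairs have f = 1 (no edge).  ``confounders`` are
    (bracket, symptom_id, activation probability) triples OR-ed into the
    symptom draw for patients of that bracket.  ``omission`` is the
    probability a present symptom goes uncharted; ``negation_prob`` the
    probability an absent concept is rendered as an explicit denial.
    """

    n_patients: int
    diseases: list[SyntheticDisease]
    symptoms: list[SyntheticSymptom]
    true_graph: dict[tuple[str, str], float] = field(default_factory=dict)
    confounders: list[tuple[str, str, float]] = field(default_factory=list)
    bracket_mix: dict[str, float] = field(
        default_factory=lambda: {
            "child": 0.10,
            "young adult": 0.20,
            "adult": 0.35,
            "senior": 0.35,
        }
    )
    omission: float = 0.0
    negation_prob: float = 0.0
    max_diseases_per_patient: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sym_ids = {s.concept_id for s in self.symptoms}
        dis_ids = {d.concept_id for d in self.diseases}
        for (d, s), f in self.true_graph.items():
            if d not in dis_ids or s not in sym_ids:
                raise ValueError(f"true_graph references unknown pair ({d}, {s})")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"failure probability out of range for ({d}, {s})")
        for bracket, s, p in self.confounders:
            if bracket not in AGE_BRACKETS or s not in sym_ids or not 0.0 <= p <= 1.0:
                raise ValueError(f"bad confounder ({bracket}, {s}, {p})")
        for sym in self.symptoms:
            if not 0.0 <= sym.leak <= 1.0:
                raise ValueError(f"leak out of range for {sym.concept_id}")
        for dis in self.diseases:
            for b, p in dis.prevalence.items():
                if b not in AGE_BRACKETS or not 0.0 <= p <= 1.0:
                    raise ValueError(f"bad prevalence ({b}, {p}) for {dis.concept_id}")
        total = sum(self.bracket_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("bracket mix must sum to 1")
        if not (0.0 <= self.omission <= 1.0 and 0.0 <= self.negation_prob <= 1.0):
            raise ValueError("omission and negation_prob must be probabilities")

    @property
    def disease_ids(self) -> list[str]:
        return [d.concept_id for d in self.diseases]

    @property
    def symptom_ids(self) -> list[str]:
        return [s.concept_id for s in self.symptoms]

    def failure_matrix(self) -> np.ndarray:
        """(n_symptoms, n_diseases) matrix of f_ij, 1 where no edge exists."""
        F = np.ones((len(self.symptoms), len(self.diseases)))
        s_idx = {s: i for i, s in enumerate(self.symptom_ids)}
        d_idx = {d: j for j, d in enumerate(self.disease_ids)}
        for (d, s), f in self.true_graph.items():
            F[s_idx[s], d_idx[d]] = f
        return F

    def leaks(self) -> np.ndarray:
        return np.array([s.leak for s in self.symptoms])


def vocabulary_from_config(config: GeneratorConfig) -> ConceptVocabulary:
    concepts = [
        Concept(d.concept_id, d.name, ROLE_DISEASE, d.aliases, d.codes)
        for d in config.diseases
    ] + [
        Concept(s.concept_id, s.name, ROLE_SYMPTOM, s.aliases) for s in config.symptoms
    ]
    return ConceptVocabulary(concepts)


def sample_disease_states(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[str]]:
    """Draw age brackets and, conditionally on them, independent diseases."""
    rng = rng or np.random.default_rng(config.seed)
    brackets_names = list(config.bracket_mix)
    probs = np.array([config.bracket_mix[b] for b in brackets_names])
    bracket_idx = rng.choice(len(brackets_names), size=config.n_patients, p=probs)
    brackets = [brackets_names[i] for i in bracket_idx]
    prev = np.array(
        [
            [d.prevalence.get(b, 0.0) for d in config.diseases]
            for b in brackets_names
        ]
    )  # (brackets, diseases)
    p = prev[bracket_idx]
    Y = (rng.random(p.shape) < p).astype(np.int8)
    cap = config.max_diseases_per_patient
    if cap is not None:
        for i in np.flatnonzero(Y.sum(axis=1) > cap):
            on = np.flatnonzero(Y[i])
            drop = rng.permutation(on)[cap:]
            Y[i, drop] = 0
    return Y, brackets


def sample_symptoms(
    disease_states: np.ndarray,
    brackets: list[str],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw symptoms from the noisy-OR conditional, confounders OR-ed in,
    then mask present symptoms with the omission probability."""
    rng = rng or np.random.default_rng(config.seed + 1)
    Y = np.asarray(disease_states, dtype=float)
    F = config.failure_matrix()
    leaks = config.leaks()
    with np.errstate(divide="ignore"):
        log_f = np.log(np.maximum(F, 1e-300))
    log_q = Y @ log_f.T + np.log1p(-np.minimum(leaks, 1 - 1e-300))[None, :]
    p = 1.0 - np.exp(log_q)
    # exact zero-failure edges force the symptom on
    forced = (Y @ (F == 0.0).T.astype(float)) > 0
    p = np.where(forced, 1.0, p)
    X = (rng.random(p.shape) < p).astype(np.int8)
    s_idx = {s: i for i, s in enumerate(config.symptom_ids)}
    bracket_arr = np.asarray(brackets)
    for bracket, sid, prob in config.confounders:
        rows = bracket_arr == bracket
        hits = rng.random(rows.sum()) < prob
        col = s_idx[sid]
        X[np.flatnonzero(rows)[hits], col] = 1
    if config.omission > 0:
        charted = rng.random(X.shape) >= config.omission
        X = (X & charted).astype(np.int8)
    return X


def build_matrix(
    disease_states: np.ndarray,
    symptom_states: np.ndarray,
    brackets: list[str],
    config: GeneratorConfig,
) -> RecordMatrix:
    n = disease_states.shape[0]
    return RecordMatrix(
        patients=[f"r{i:06d}" for i in range(n)],
        concepts=config.disease_ids + config.symptom_ids,
        roles=[ROLE_DISEASE] * len(config.diseases)
        + [ROLE_SYMPTOM] * len(config.symptoms),
        cells=np.hstack([disease_states, symptom_states]),
        age_brackets=list(brackets),
    )


def render_text_records(
    matrix: RecordMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[TextRecord]:
    """Render matrix rows as free-text records with codes and denials.

    Every positive concept appears through a random alias in a positive
    template (sentence-terminated, so inserted denials cannot leak scope
    onto it); positive diseases with code mappings also emit their first
    code.  With probability ``negation_prob`` an absent concept is rendered
    as an explicit denial.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    concepts = {c.concept_id: c for c in vocabulary_from_config(config).concepts}
    records: list[TextRecord] = []
    for row, rid in enumerate(matrix.patients):
        sentences: dict[str, list[str]] = {f: [] for f in TEXT_FIELDS}
        codes: list[str] = []
        for col, cid in enumerate(matrix.concepts):
            concept = concepts[cid]
            aliases = concept.effective_aliases
            if not aliases:
                raise ValueError(f"concept {cid} has no alias to render")
            if matrix.cells[row, col]:
                alias = aliases[rng.integers(len(aliases))]
                tmpl = POSITIVE_TEMPLATES[rng.integers(len(POSITIVE_TEMPLATES))]
                fld = TEXT_FIELDS[rng.integers(len(TEXT_FIELDS))]
                sentences[fld].append(tmpl.format(alias))
                if concept.role == ROLE_DISEASE and concept.codes:
                    codes.append(concept.codes[0])
            elif config.negation_prob and rng.random() < config.negation_prob:
                alias = aliases[rng.integers(len(aliases))]
                tmpl = NEGATION_TEMPLATES[rng.integers(len(NEGATION_TEMPLATES))]
                fld = TEXT_FIELDS[rng.integers(len(TEXT_FIELDS))]
                sentences[fld].append(tmpl.format(alias))
        records.append(
            TextRecord(
                record_id=rid,
                age_bracket=matrix.age_brackets[row],
                fields={f: " ".join(s) for f, s in sentences.items() if s},
                codes=codes,
            )
        )
    return records


def make_ground_truth_graph(config: GeneratorConfig) -> KnowledgeGraph:
    """Generating edges scored on the importance scale (1 - failure)."""
    edges = [
        (d, s, 1.0 - f) for (d, s), f in config.true_graph.items() if f < 1.0
    ]
    return KnowledgeGraph(edges=edges, provenance={"model": "ground_truth"})


@dataclass
class SyntheticCorpus:
    matrix: RecordMatrix
    records: list[TextRecord]
    truth: KnowledgeGraph
    vocabulary: ConceptVocabulary


def generate_corpus(
    config: GeneratorConfig, render_text: bool = True
) -> SyntheticCorpus:
    """Sample a full corpus: matrix, rendered records, truth graph, vocabulary."""
    rng = np.random.default_rng(config.seed)
    Y, brackets = sample_disease_states(config, rng)
    X = sample_symptoms(Y, brackets, config, rng)
    matrix = build_matrix(Y, X, brackets, config)
    records = render_text_records(matrix, config, rng) if render_text else []
    return SyntheticCorpus(
        matrix=matrix,
        records=records,
        truth=make_ground_truth_graph(config),
        vocabulary=vocabulary_from_config(config),
    )


# -- demo configuration and JSON round-trip --------------------------------


def demo_config(n_patients: int = 5000, seed: int = 7) -> GeneratorConfig:
    """A small but structured corpus: 6 diseases, 12 symptoms, one senior
    confounder, mild omission and denial rates."""
    diseases = [
        SyntheticDisease(
            "d_appendicitis",
            "appendicitis",
            {"child": 0.02, "young adult": 0.04, "adult": 0.03, "senior": 0.02},
            aliases=("appy",),
            codes=("540.9",),
        ),
        SyntheticDisease(
            "d_gallstones",
            "gallstones",
            {"child": 0.001, "young adult": 0.02, "adult": 0.05, "senior": 0.06},
            aliases=("cholelithiasis",),
            codes=("574.20",),
        ),
        SyntheticDisease(
            "d_kidney_stone",
            "kidney stone",
            {"child": 0.002, "young adult": 0.03, "adult": 0.06, "senior": 0.04},
            aliases=("nephrolithiasis", "renal calculus"),
            codes=("592.0",),
        ),
        SyntheticDisease(
            "d_flu",
            "influenza",
            {"child": 0.10, "young adult": 0.07, "adult": 0.06, "senior": 0.08},
            aliases=("flu",),
            codes=("487.1",),
        ),
        SyntheticDisease(
            "d_pneumonia",
            "pneumonia",
            {"child": 0.03, "young adult": 0.02, "adult": 0.03, "senior": 0.09},
            codes=("486",),
        ),
        SyntheticDisease(
            "d_stroke",
            "stroke",
            {"child": 0.0, "young adult": 0.002, "adult": 0.01, "senior": 0.07},
            aliases=("cva",),
            codes=("434.91",),
        ),
    ]
    symptoms = [
        SyntheticSymptom("s_abd_pain", "abdominal pain", 0.05, aliases=("belly ache",)),
        SyntheticSymptom("s_nausea", "nausea", 0.06),
        SyntheticSymptom("s_vomiting", "vomiting", 0.03, aliases=("emesis",)),
        SyntheticSymptom("s_fever", "fever", 0.04, aliases=("febrile",)),
        SyntheticSymptom("s_cough", "cough", 0.05),
        SyntheticSymptom("s_flank_pain", "flank pain", 0.01),
        SyntheticSymptom("s_hematuria", "blood in urine", 0.005, aliases=("hematuria",)),
        SyntheticSymptom("s_jaundice", "yellow skin", 0.002, aliases=("jaundice",)),
        SyntheticSymptom("s_weakness", "weakness", 0.04),
        SyntheticSymptom("s_slurred_speech", "slurred speech", 0.002),
        SyntheticSymptom("s_myalgia", "muscle ache", 0.03, aliases=("myalgia",)),
        SyntheticSymptom("s_confusion", "confusion", 0.01),
    ]
    true_graph = {
        ("d_appendicitis", "s_abd_pain"): 0.25,
        ("d_appendicitis", "s_nausea"): 0.55,
        ("d_appendicitis", "s_fever"): 0.75,
        ("d_gallstones", "s_abd_pain"): 0.35,
        ("d_gallstones", "s_nausea"): 0.55,
        ("d_gallstones", "s_vomiting"): 0.65,
        ("d_gallstones", "s_jaundice"): 0.85,
        ("d_kidney_stone", "s_flank_pain"): 0.30,
        ("d_kidney_stone", "s_hematuria"): 0.70,
        ("d_kidney_stone", "s_nausea"): 0.70,
        ("d_flu", "s_fever"): 0.35,
        ("d_flu", "s_cough"): 0.45,
        ("d_flu", "s_myalgia"): 0.55,
        ("d_pneumonia", "s_fever"): 0.40,
        ("d_pneumonia", "s_cough"): 0.30,
        ("d_stroke", "s_weakness"): 0.40,
        ("d_stroke", "s_slurred_speech"): 0.55,
    }
    return GeneratorConfig(
        n_patients=n_patients,
        diseases=diseases,
        symptoms=symptoms,
        true_graph=true_graph,
        confounders=[("senior", "s_confusion", 0.08)],
        omission=0.05,
        negation_prob=0.25,
        seed=seed,
    )


def config_to_json(config: GeneratorConfig, path: str | Path) -> None:
    doc = {
        "n_patients": config.n_patients,
        "diseases": [asdict(d) for d in config.diseases],
        "symptoms": [asdict(s) for s in config.symptoms],
        "true_graph": [
            {"disease": d, "symptom": s, "failure": f}
            for (d, s), f in sorted(config.true_graph.items())
        ],
        "confounders": [list(c) for c in config.confounders],
        "bracket_mix": config.bracket_mix,
        "omission": config.omission,
        "negation_prob": config.negation_prob,
        "max_diseases_per_patient": config.max_diseases_per_patient,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def config_from_json(path: str | Path) -> GeneratorConfig:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return GeneratorConfig(
        n_patients=int(doc["n_patients"]),
        diseases=[
            SyntheticDisease(
                concept_id=d["concept_id"],
                name=d["name"],
                prevalence=dict(d["prevalence"]),
                aliases=tuple(d.get("aliases", ())),
                codes=tuple(d.get("codes", ())),
            )
            for d in doc["diseases"]
        ],
        symptoms=[
            SyntheticSymptom(
                concept_id=s["concept_id"],
                name=s["name"],
                leak=float(s["leak"]),
                aliases=tuple(s.get("aliases", ())),
            )
            for s in doc["symptoms"]
        ],
        true_graph={
            (e["disease"], e["symptom"]): float(e["failure"])
            for e in doc.get("true_graph", [])
        },
        confounders=[tuple(c) for c in doc.get("confounders", [])],
        bracket_mix=dict(doc.get("bracket_mix", {})) or None
        or {"child": 0.10, "young adult": 0.20, "adult": 0.35, "senior": 0.35},
        omission=float(doc.get("omission", 0.0)),
        negation_prob=float(doc.get("negation_prob", 0.0)),
        max_diseases_per_patient=doc.get("max_diseases_per_patient"),
        seed=int(doc.get("seed", 0)),
    )
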