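import numpy as np
import pytest

from emrkg.matrix import RecordMatrix
from emrkg.vocabulary import Concept, ConceptVocabulary


@pytest.fixture
def small_vocabulary() -> ConceptVocabulary:
    return ConceptVocabulary(
        [
            Concept("d_appendicitis", "appendicitis", "disease", ("appy",), ("540.9",)),
            Concept(
                "d_gallstones",
                "gallstones",
                "disease",
                ("cholelithiasis", "gall stones"),
                ("574.2",),
            ),
            Concept("s_flank_pain", "flank pain", "symptom"),
            Concept("s_pain", "pain", "symptom"),
            Concept("s_nausea", "nausea", "symptom"),
            Concept("s_fever", "fever", "symptom", ("febrile",)),
        ]
    )


def make_matrix(Y, X, disease_ids=None, symptom_ids=None, brackets=None):
    """Assemble a RecordMatrix from disease and symptom blocks."""
    Y = np.atleast_2d(np.asarray(Y, dtype=np.int8))
    X = np.atleast_2d(np.asarray(X, dtype=np.int8))
    n, d = Y.shape
    s = X.shape[1]
    disease_ids = disease_ids or [f"d{j}" for j in range(d)]
    symptom_ids = symptom_ids or [f"s{i}" for i in range(s)]
    return RecordMatrix(
        patients=[f"r{i:05d}" for i in range(n)],
        concepts=list(disease_ids) + list(symptom_ids),
        roles=["disease"] * d + ["symptom"] * s,
        cells=np.hstack([Y, X]),
        age_brackets=list(brackets) if brackets is not None else None or ["adult"] * n,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
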