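"""Binary patients-by-concepts matrix shared by extraction and model fitting.

The matrix is the central in-memory container of the pipeline: one row per
patient visit, one column per concept (disease or symptom), cell 1 meaning the
record carries a positive, non-negated mention of the concept (or a mapped
diagnosis code).  On disk it is stored in Matrix Market coordinate format as
concepts x patients — the co-occurrence-matrix dialect — with two sibling TSV
index files carrying the patient and concept axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

ROLE_DISEASE = "disease"
ROLE_SYMPTOM = "symptom"


@dataclass
class RecordMatrix:
    """Binary indicator matrix of concept occurrences per patient record.

    Parameters
    ----------
    patients : list of str
        Ordered record identifiers (rows).
    concepts : list of str
        Ordered concept identifiers (columns).
    roles : list of str
        Per-column role, ``"disease"`` or ``"symptom"``.
    cells : ndarray of shape (n_patients, n_concepts)
        Strictly 0/1 entries.
    age_brackets : list of str
        Per-patient age bracket label (``"unknown"`` allowed).
    """

    patients: list[str]
    concepts: list[str]
    roles: list[str]
    cells: np.ndarray
    age_brackets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.shape != (len(self.patients), len(self.concepts)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.patients)} patients x {len(self.concepts)} concepts"
            )
        if len(self.roles) != len(self.concepts):
            raise ValueError("one role per concept column required")
        bad_roles = set(self.roles) - {ROLE_DISEASE, ROLE_SYMPTOM}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        if self.cells.size and not np.isin(self.cells, (0, 1)).all():
            raise ValueError("matrix cells must be binary 0/1")
        self.cells = self.cells.astype(np.int8, copy=False)
        if not self.age_brackets:
            self.age_brackets = ["unknown"] * len(self.patients)
        if len(self.age_brackets) != len(self.patients):
            raise ValueError("one age bracket per patient required")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate record ids in matrix")

    # -- axis helpers -----------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def disease_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.roles) == ROLE_DISEASE)

    @property
    def symptom_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.roles) == ROLE_SYMPTOM)

    @property
    def disease_ids(self) -> list[str]:
        return [self.concepts[i] for i in self.disease_indices]

    @property
    def symptom_ids(self) -> list[str]:
        return [self.concepts[i] for i in self.symptom_indices]

    def column(self, concept_id: str) -> np.ndarray:
        return self.cells[:, self.concepts.index(concept_id)]

    def marginals(self) -> np.ndarray:
        """Per-concept positive-mention counts (column sums)."""
        return self.cells.sum(axis=0)

    def disease_block(self) -> np.ndarray:
        return self.cells[:, self.disease_indices]

    def symptom_block(self) -> np.ndarray:
        return self.cells[:, self.symptom_indices]

    def subset_concepts(self, keep: np.ndarray) -> "RecordMatrix":
        keep = np.asarray(keep)
        return RecordMatrix(
            patients=list(self.patients),
            concepts=[self.concepts[i] for i in keep],
            roles=[self.roles[i] for i in keep],
            cells=self.cells[:, keep].copy(),
            age_brackets=list(self.age_brackets),
        )

    def cooccurrence_counts(self) -> np.ndarray:
        """(n_diseases, n_symptoms) counts of records with both concepts on."""
        d = self.disease_block().astype(np.int64)
        s = self.symptom_block().astype(np.int64)
        return d.T @ s

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordMatrix):
            return NotImplemented
        return (
            self.patients == other.patients
            and self.concepts == other.concepts
            and self.roles == other.roles
            and self.age_brackets == other.age_brackets
            and np.array_equal(self.cells, other.cells)
        )


def _index_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.patients.tsv"), Path(f"{stem}.concepts.tsv")


def save_matrix(matrix: RecordMatrix, mtx_path: str | Path) -> None:
    """Write a RecordMatrix as Matrix Market (concepts x patients) plus TSV axes."""
    mtx_path = Path(mtx_path)
    mtx_path.parent.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.cells.T)
    mmwrite(str(mtx_path), coo, field="integer")
    patients_path, concepts_path = _index_paths(mtx_path)
    pd.DataFrame(
        {"record_id": matrix.patients, "age_bracket": matrix.age_brackets}
    ).to_csv(patients_path, sep="\t", index=False)
    pd.DataFrame({"concept_id": matrix.concepts, "role": matrix.roles}).to_csv(
        concepts_path, sep="\t", index=False
    )


def load_matrix(mtx_path: str | Path) -> RecordMatrix:
    """Read a RecordMatrix written by :func:`save_matrix`."""
    mtx_path = Path(mtx_path)
    patients_path, concepts_path = _index_paths(mtx_path)
    cells = np.asarray(mmread(str(mtx_path)).todense()).T
    patients = pd.read_csv(patients_path, sep="\t", dtype=str)
    concepts = pd.read_csv(concepts_path, sep="\t", dtype=str)
    return RecordMatrix(
        patients=patients["record_id"].tolist(),
        concepts=concepts["concept_id"].tolist(),
        roles=concepts["role"].tolist(),
        cells=cells,
        age_brackets=patients["age_bracket"].tolist(),
    )
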