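"""Relationship matrices over an ordered list of individuals.

A :class:`RelationshipMatrix` is a dense symmetric matrix of additive
relationship coefficients together with the ordered individual ids it is
indexed by and a ``kind`` tag recording how it was built (pedigree ``A``,
whole-genome ``G``, single-chromosome ``G_c``, complement ``G_o``, or a
beta-adjusted ``G*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: Allowed kind tags.
KINDS = ("pedigree_A", "genomic_G", "chromosome_Gc", "complement_Go", "adjusted_Gstar")


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix tagged by provenance.

    Parameters
    ----------
    ids
        Ordered individual identifiers; one per row/column.
    values
        Dense symmetric ``(n, n)`` array of relationship coefficients.
    kind
        One of :data:`KINDS`.
    meta
        Free-form provenance (marker count, chromosome, beta used, ...).
    """

    ids: list
    values: np.ndarray
    kind: str = "genomic_G"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputError(f"relationship matrix must be square, got {self.values.shape}")
        if len(self.ids) != self.values.shape[0]:
            raise InputError("id list length does not match matrix dimension")
        if self.kind not in KINDS:
            raise InputError(f"unknown relationship kind {self.kind!r}")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate ids in relationship matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence) -> np.ndarray:
        pos = {ind: i for i, ind in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"id {exc.args[0]!r} not present in relationship matrix") from None

    def subset(self, ids: Sequence) -> "RelationshipMatrix":
        """Principal submatrix in the requested id order; kind preserved."""
        idx = self.index_of(ids)
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  kind=self.kind, meta=dict(self.meta))

    # ---- i/o -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        """Symmetric-matrix TSV: header row of ids, one row per individual."""
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, kind: str = "genomic_G") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), kind=kind)

    def to_long(self) -> pd.DataFrame:
        """Lower-triangle long format (id1, id2, value), diagonal included."""
        i, j = np.tril_indices(self.n)
        return pd.DataFrame({
            "id1": [self.ids[a] for a in i],
            "id2": [self.ids[b] for b in j],
            "value": self.values[i, j],
        })


def subset_matrix(matrix: RelationshipMatrix, ids: Sequence) -> RelationshipMatrix:
    """Functional alias for :meth:`RelationshipMatrix.subset`."""
    return matrix.subset(ids)
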