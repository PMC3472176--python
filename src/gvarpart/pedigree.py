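"""Pedigrees and the additive (numerator) relationship matrix A.

``A`` holds expected additive relationships — twice the kinship coefficient —
derived from probabilities of identity by descent. It is built with the
tabular method: individuals are processed in an order where parents precede
offspring, and

    a_ii = 1 + 0.5 * a_{sire(i), dam(i)}        (missing parent contributes 0)
    a_ij = 0.5 * (a_{j, sire(i)} + a_{j, dam(i)})   for j processed before i.

Missing parents are treated as unknown, unrelated, non-inbred founders.
Storage is dense; the intended scale is the (at most a few thousand)
phenotyped and genotyped individuals, optionally after restricting the
pedigree to their ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PedigreeError
from .relmatrix import RelationshipMatrix

MISSING = -1  # internal index code for an unknown parent


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    ``sire_idx`` / ``dam_idx`` hold the positional index of each individual's
    parents in ``ids`` (or :data:`MISSING`). Construction validates id
    uniqueness and sorts records so that parents precede offspring, raising
    :class:`PedigreeError` on cycles.
    """

    ids: list
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    sex: Optional[np.ndarray] = None  # 'M'/'F' per individual, optional
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self) -> np.ndarray:
        return (self.sire_idx == MISSING) & (self.dam_idx == MISSING)

    @classmethod
    def from_records(cls, records: Sequence[tuple], sex: Optional[Sequence] = None) -> "Pedigree":
        """Build from (id, sire, dam) triples; ``None``/''/0 marks a missing parent.

        Records may appear in any order; a topological sort is applied. Parents
        referenced but never listed as individuals are rejected.
        """
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise PedigreeError(f"duplicate individual id(s): {list(dup[dup > 1].index)}")
        pos = {ind: i for i, ind in enumerate(ids)}

        def parent_index(p, child):
            if p is None or p == "" or p == 0 or (isinstance(p, float) and np.isnan(p)):
                return MISSING
            if p not in pos:
                raise PedigreeError(f"parent {p!r} of {child!r} is not listed as an individual")
            return pos[p]

        sire = np.array([parent_index(r[1], r[0]) for r in records], dtype=int)
        dam = np.array([parent_index(r[2], r[0]) for r in records], dtype=int)
        for i in range(len(ids)):
            if sire[i] == i or dam[i] == i:
                raise PedigreeError(f"individual {ids[i]!r} is its own parent")

        order = _topological_order(sire, dam, ids)
        inv = np.empty(len(order), dtype=int)
        inv[order] = np.arange(len(order))
        remap = np.concatenate([inv, [MISSING]])  # MISSING (-1) maps to itself
        sex_arr = None
        if sex is not None:
            sex_arr = np.asarray(sex, dtype=object)[order]
        return cls(ids=[ids[i] for i in order], sire_idx=remap[sire[order]],
                   dam_idx=remap[dam[order]], sex=sex_arr)

    def to_frame(self) -> pd.DataFrame:
        def name(idx):
            return [self.ids[i] if i != MISSING else "" for i in idx]
        return pd.DataFrame({"id": self.ids, "sire": name(self.sire_idx),
                             "dam": name(self.dam_idx)})

    def parents_of(self, ind) -> tuple:
        i = self.ids.index(ind)
        s, d = self.sire_idx[i], self.dam_idx[i]
        return (self.ids[s] if s != MISSING else None,
                self.ids[d] if d != MISSING else None)


def _topological_order(sire: np.ndarray, dam: np.ndarray, ids: list) -> list:
    """Kahn's algorithm over the parent->offspring DAG; detects cycles."""
    n = len(ids)
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != MISSING:
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    order = []
    while queue:
        # pop smallest original index for a deterministic order
        i = min(queue)
        queue.remove(i)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        stuck = [ids[i] for i in range(n) if indeg[i] > 0]
        raise PedigreeError(f"pedigree contains a cycle involving: {stuck[:5]}")
    return order


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    Returns a :class:`RelationshipMatrix` of kind ``pedigree_A``. Diagonal
    entries are ``1 + F_i`` with ``F_i`` the inbreeding coefficient, so they
    lie in ``[1, 2]``.
    """
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s != MISSING:
                row += A[s, :i]
            if d != MISSING:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != MISSING and d != MISSING) else 0.0)
    return RelationshipMatrix(list(ped.ids), A, kind="pedigree_A",
                              meta={"n_individuals": n})


def restrict_to_ancestors(ped: Pedigree, ids: Sequence) -> Pedigree:
    """Sub-pedigree containing ``ids`` and all their ancestors.

    Useful before :func:`build_A` when only a subset of a large pedigree is
    phenotyped: A restricted to the subset only needs the ancestor closure.
    """
    keep = set()
    idx = {ind: i for i, ind in enumerate(ped.ids)}
    stack = []
    for ind in ids:
        if ind not in idx:
            raise InputError(f"id {ind!r} not in pedigree")
        stack.append(idx[ind])
    while stack:
        i = stack.pop()
        if i in keep:
            continue
        keep.add(i)
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p != MISSING:
                stack.append(p)
    kept = sorted(keep)
    records = []
    kept_set = set(kept)
    for i in kept:
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        records.append((ped.ids[i],
                        ped.ids[s] if s in kept_set else None,
                        ped.ids[d] if d in kept_set else None))
    return Pedigree.from_records(records)
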