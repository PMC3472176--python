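"""Marker QC and genomic relationship matrices (GRMs).

The GRM follows the classical centered allele-count construction

    G = (M - P)(M - P)' / (2 * sum_j p_j (1 - p_j))

where ``M`` (n x m) counts copies of the second allele (0/1/2), ``P``
broadcasts twice the second-allele frequency ``2 p_j`` per column, and the
denominator puts G on the same scale as the pedigree matrix A. G measures
realized identity by state, in contrast to A's expected identity by descent.

QC mirrors routine chip handling: markers with minor allele frequency below a
threshold are dropped, and "non-informative" markers — those whose genotype
vector is an exact affine function of an earlier marker (duplicates,
complement-coded copies) — are removed because they contribute no independent
information to G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegeneracyError, InputError, QCError
from .relmatrix import RelationshipMatrix


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-count codes with a marker map.

    ``codes`` is float ``(n, m)`` with entries in {0, 1, 2} or NaN for a
    missing call. Marker metadata (``chrom``, ``pos``) is kept sorted by
    (chromosome, position); positions are 1-based bp and must be strictly
    increasing within a chromosome.
    """

    ids: list
    marker_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    codes: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.marker_ids = list(self.marker_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.ids), len(self.marker_ids)):
            raise InputError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.marker_ids)} markers")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise InputError(
                f"genotype code {self.codes[tuple(bad)]!r} at individual "
                f"{self.ids[bad[0]]!r}, marker {self.marker_ids[bad[1]]!r} "
                "is outside {0,1,2,NA}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise InputError(f"positions not strictly increasing on chromosome {c!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.marker_ids)

    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.marker_ids, "chrom": self.chrom,
                             "pos": self.pos})

    def select_markers(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return GenotypeMatrix(
            self.ids, [self.marker_ids[j] for j in idx], self.chrom[idx],
            self.pos[idx], self.codes[:, idx], meta=dict(self.meta))

    def select_individuals(self, ids: Sequence) -> "GenotypeMatrix":
        pos = {ind: i for i, ind in enumerate(self.ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as exc:
            raise InputError(f"individual {exc.args[0]!r} not genotyped") from None
        return GenotypeMatrix(list(ids), self.marker_ids, self.chrom, self.pos,
                              self.codes[idx, :], meta=dict(self.meta))

    def chromosomes(self) -> np.ndarray:
        return pd.unique(self.chrom)


@dataclass
class QCReport:
    """Accounting of marker QC: input = removed_maf + removed_dependence + retained."""

    n_input: int
    n_removed_maf: int
    n_removed_dependence: int
    n_retained: int
    removals: pd.DataFrame  # columns: marker, reason, detail

    def __post_init__(self):
        if self.n_input != self.n_removed_maf + self.n_removed_dependence + self.n_retained:
            raise QCError("QC accounting identity violated")

    def __str__(self):
        return (f"markers: {self.n_input} input, {self.n_removed_maf} removed "
                f"(MAF), {self.n_removed_dependence} removed (linear dependence), "
                f"{self.n_retained} retained")


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Second-allele frequency per marker, p_j = mean(codes_j) / 2 over non-missing calls."""
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(~np.isnan(geno.codes), axis=0)
        if np.any(n_obs == 0):
            j = int(np.argmin(n_obs))
            raise QCError(f"marker {geno.marker_ids[j]!r} has no non-missing calls")
        return np.nanmean(geno.codes, axis=0) / 2.0


def _affine_key(col: np.ndarray) -> bytes:
    """Canonical byte key equal for columns related by an exact affine map.

    Centering on the first non-missing entry removes the offset; dividing by
    the first non-zero centered entry removes the scale. Missing entries are
    encoded with a sentinel so only identical missingness patterns can match.
    """
    miss = np.isnan(col)
    obs = col[~miss]
    c = col - obs[0]
    nz = np.flatnonzero(~miss & (c != 0))
    if nz.size:
        c = c / c[nz[0]]
    out = np.round(c, 9) + 0.0  # normalize -0.0
    out[miss] = -128.0
    return out.tobytes()


def qc_markers(geno: GenotypeMatrix, maf_threshold: float = 0.01):
    """MAF and exact linear-dependence filtering.

    Removes markers with ``min(p, 1-p) < maf_threshold`` (strict, so a marker
    at exactly the threshold is retained), then scans the remaining markers in
    genome order and removes any whose genotype vector is an exact affine
    function of an earlier retained marker — this covers duplicated columns
    and complement-coded copies (``2 - m``).

    Returns ``(filtered GenotypeMatrix, QCReport)``.
    """
    p = allele_frequencies(geno)
    maf = np.minimum(p, 1.0 - p)
    maf_fail = maf < maf_threshold
    removals = [(geno.marker_ids[j], "maf", f"maf={maf[j]:.4g}")
                for j in np.flatnonzero(maf_fail)]

    seen: dict = {}
    dep_fail = np.zeros(geno.m, dtype=bool)
    for j in range(geno.m):
        if maf_fail[j]:
            continue
        key = _affine_key(geno.codes[:, j])
        if key in seen:
            dep_fail[j] = True
            removals.append((geno.marker_ids[j], "dependence",
                             f"affine function of {geno.marker_ids[seen[key]]}"))
        else:
            seen[key] = j

    keep = ~(maf_fail | dep_fail)
    if not keep.any():
        raise QCError("no markers retained after QC")
    report = QCReport(
        n_input=geno.m,
        n_removed_maf=int(maf_fail.sum()),
        n_removed_dependence=int(dep_fail.sum()),
        n_retained=int(keep.sum()),
        removals=pd.DataFrame(removals, columns=["marker", "reason", "detail"]),
    )
    return geno.select_markers(keep), report


def build_G(geno: GenotypeMatrix, freqs: Optional[np.ndarray] = None,
            kind: str = "genomic_G", denominator: Optional[float] = None) -> RelationshipMatrix:
    """Genomic relationship matrix from centered allele counts.

    ``freqs`` defaults to the observed sample frequencies. Missing codes are
    mean-imputed to ``2 p_j`` before centering (they then contribute zero to
    the cross-product). ``denominator`` overrides ``2 * sum p_j (1-p_j)``,
    which is used when chromosome-split matrices should share the
    whole-genome scale.
    """
    if geno.m < 1:
        raise DegeneracyError("cannot build G from an empty marker set")
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (geno.m,):
        raise InputError("frequency vector length does not match marker count")
    het = 2.0 * np.sum(p * (1.0 - p))
    denom = het if denominator is None else float(denominator)
    if denom <= 0:
        raise DegeneracyError("sum of marker heterozygosities is zero; G undefined")
    W = geno.codes - 2.0 * p  # centered; broadcasting over columns
    W = np.where(np.isnan(W), 0.0, W)  # mean imputation after centering
    G = (W @ W.T) / denom
    return RelationshipMatrix(geno.ids, G, kind=kind,
                              meta={"m_markers": geno.m, "denominator": denom})


def split_G_by_chromosome(geno: GenotypeMatrix, chrom,
                          shared_denominator: bool = False):
    """G from one chromosome's markers and G from all remaining markers.

    Each matrix is normalized by its own heterozygosity sum by default;
    ``shared_denominator=True`` uses the whole-genome ``2*sum p(1-p)`` for
    both, which changes only the scale of the per-chromosome variance.
    """
    on = geno.chrom == chrom
    if on.sum() == 0:
        raise InputError(f"chromosome {chrom!r} has no markers")
    if on.sum() < 2:
        raise DegeneracyError(f"chromosome {chrom!r} has fewer than 2 markers")
    if (~on).sum() < 2:
        raise DegeneracyError("complement marker set has fewer than 2 markers")
    denom = None
    if shared_denominator:
        p = allele_frequencies(geno)
        denom = 2.0 * np.sum(p * (1.0 - p))
    G_c = build_G(geno.select_markers(on), kind="chromosome_Gc", denominator=denom)
    G_o = build_G(geno.select_markers(~on), kind="complement_Go", denominator=denom)
    G_c.meta["chromosome"] = chrom
    G_o.meta["excluded_chromosome"] = chrom
    return G_c, G_o
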