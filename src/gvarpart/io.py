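"""Readers and writers for the package's plain-text formats.

Formats:

* pedigree CSV/TSV with columns ``id, sire, dam``; empty field or 0 = missing
* genotype TSV: rows = individuals (first column ``id``), header = marker
  ids; companion marker-map TSV with columns ``marker, chrom, pos``
* PLINK ``.raw`` dialect: ``FID IID PAT MAT SEX PHENOTYPE`` then one
  allele-dosage column per marker (``name_A``), ``NA`` = missing
* phenotype TSV: ``id, trait, y, weight``
* symmetric-matrix TSV and long format: see
  :meth:`gvarpart.relmatrix.RelationshipMatrix.to_tsv` / ``to_long``
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .grm import GenotypeMatrix
from .pedigree import Pedigree

__all__ = ["read_pedigree", "write_pedigree", "read_genotypes", "write_genotypes",
           "read_raw", "write_raw", "read_phenotypes", "write_phenotypes"]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".raw")) else ","


def read_pedigree(path) -> Pedigree:
    """Read and topologically sort a pedigree file (columns id, sire, dam)."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False,
                     comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise InputError(f"pedigree file {path} lacks column {col!r}")

    def clean(v):
        v = v.strip()
        return None if v in ("", "0", "NA", ".") else v

    records = [(row["id"].strip(), clean(row["sire"]), clean(row["dam"]))
               for _, row in df.iterrows()]
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_phenotypes(path, trait=None) -> pd.DataFrame:
    """Phenotype TSV (id, trait, y, weight); optionally filter to one trait."""
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "y", "weight"):
        if col not in df.columns:
            raise InputError(f"phenotype file {path} lacks column {col!r}")
    df["id"] = df["id"].astype(str)
    if trait is not None:
        if "trait" not in df.columns:
            raise InputError("phenotype file has no 'trait' column to filter on")
        df = df[df["trait"] == trait].reset_index(drop=True)
        if df.empty:
            raise InputError(f"no records for trait {trait!r}")
    return df


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep=_sep(path), index=False)


def _read_marker_map(map_path) -> pd.DataFrame:
    m = pd.read_csv(map_path, sep=_sep(map_path), comment="#")
    m.columns = [c.strip().lower() for c in m.columns]
    for col in ("marker", "chrom", "pos"):
        if col not in m.columns:
            raise InputError(f"marker map {map_path} lacks column {col!r}")
    return m


def _assemble(ids, marker_ids, codes, map_path) -> GenotypeMatrix:
    mmap = _read_marker_map(map_path).set_index("marker")
    missing = [mk for mk in marker_ids if mk not in mmap.index]
    extra = [mk for mk in mmap.index if mk not in set(marker_ids)]
    if missing or extra:
        raise InputError(
            f"marker map mismatch: {len(missing)} genotyped markers missing from map "
            f"(e.g. {missing[:3]}), {len(extra)} map-only markers (e.g. {extra[:3]})")
    chrom = mmap.loc[marker_ids, "chrom"].to_numpy()
    pos = mmap.loc[marker_ids, "pos"].to_numpy()
    order = np.lexsort((pos, chrom))
    return GenotypeMatrix([str(i) for i in ids],
                          [marker_ids[j] for j in order],
                          chrom[order], pos[order], codes[:, order])


def read_genotypes(path, map_path) -> GenotypeMatrix:
    """Genotype TSV (rows = individuals) plus marker-map TSV.

    Markers are reordered by (chromosome, position); codes outside
    {0, 1, 2, NA} are rejected.
    """
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    marker_ids = list(df.columns[1:])
    codes = df[marker_ids].to_numpy(dtype=float)
    return _assemble(ids, marker_ids, codes, map_path)


def write_genotypes(geno: GenotypeMatrix, path, map_path) -> None:
    out = pd.DataFrame(geno.codes, columns=geno.marker_ids)
    out.insert(0, "id", geno.ids)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    geno.marker_map().to_csv(map_path, sep="\t", index=False)


_ALLELE_SUFFIX = re.compile(r"_[ACGT]$")


def read_raw(path, map_path) -> GenotypeMatrix:
    """PLINK ``.raw`` allele-dosage dialect.

    Expects the standard six leading columns; marker columns may carry a
    counted-allele suffix (``name_A``) which is stripped to match the map.
    """
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != lead:
        raise InputError(f".raw file {path} lacks the standard leading columns {lead}")
    marker_cols = list(df.columns[6:])
    marker_ids = [_ALLELE_SUFFIX.sub("", c) for c in marker_cols]
    codes = df[marker_cols].to_numpy(dtype=float)
    return _assemble(df["IID"].astype(str).tolist(), marker_ids, codes, map_path)


def write_raw(geno: GenotypeMatrix, path, map_path=None) -> None:
    out = pd.DataFrame(geno.codes, columns=[f"{m}_A" for m in geno.marker_ids])
    for col, val in zip(("PHENOTYPE", "SEX", "MAT", "PAT"), (-9, 0, 0, 0)):
        out.insert(0, col, val)
    out.insert(0, "IID", geno.ids)
    out.insert(0, "FID", geno.ids)
    out.to_csv(path, sep=" ", index=False, na_rep="NA")
    if map_path is not None:
        geno.marker_map().to_csv(map_path, sep="\t", index=False)


def stamp_header(path, seed, note: str = "") -> None:
    """Prepend a provenance comment line (generator version + seed) to a text file."""
    from . import __version__

    p = Path(path)
    body = p.read_text()
    p.write_text(f"# gvarpart {__version__} seed={seed} {note}\n" + body)
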