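"""Drivers for the four-model variance partition and its summary arithmetic.

Model 1 is the classical pedigree animal model (term ``a`` with covariance
A); model 2 the genomic model (term ``g`` with covariance G); model 3 fits
both, splitting total additive variance into a marker-tagged genomic part
and a residual polygenic part; model 4 replaces the single genomic term with
one chromosome's matrix ``G_c`` plus the complement ``G_o``, run once per
chromosome to partition genomic variance along the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegeneracyError, InputError
from .grm import GenotypeMatrix, build_G, split_G_by_chromosome
from .relmatrix import RelationshipMatrix
from .reml import REMLResults, VarianceComponentModel

__all__ = ["ModelResult", "ChromosomePartition", "fit_model", "chromosome_scan",
           "genomic_share", "model_total_ratio", "regress_variance_on_length",
           "MODEL_TERMS"]

#: random-term labels per model id
MODEL_TERMS = {1: ("a",), 2: ("g",), 3: ("g", "a"), 4: ("g_c", "g_o", "a")}


@dataclass
class ModelResult:
    """One fitted model for one trait."""

    trait: str
    model: int
    results: REMLResults
    vr: float
    chromosome: Optional[object] = None

    @property
    def params(self) -> pd.Series:
        return self.results.params

    def to_frame(self) -> pd.DataFrame:
        df = self.results.to_frame()
        df.insert(0, "trait", self.trait)
        df.insert(1, "model", self.model)
        df["vr"] = self.vr
        if self.chromosome is not None:
            df["chromosome"] = self.chromosome
        return df


def _check_phen(phen: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "y", "weight"}
    missing = required - set(phen.columns)
    if missing:
        raise InputError(f"phenotype table lacks columns: {sorted(missing)}")
    return phen


def fit_model(phen: pd.DataFrame, model: int, A: Optional[RelationshipMatrix] = None,
              G: Optional[RelationshipMatrix] = None,
              G_c: Optional[RelationshipMatrix] = None,
              G_o: Optional[RelationshipMatrix] = None,
              trait: str = "trait", chromosome=None, **fit_kw) -> ModelResult:
    """Fit one of the four models to a phenotype table (id, y, weight).

    The matrices are aligned to the phenotyped individuals by id; a matrix
    may cover a superset of them.
    """
    if model not in MODEL_TERMS:
        raise ConfigError(f"model must be one of {sorted(MODEL_TERMS)}, got {model!r}")
    phen = _check_phen(phen)
    supplied = {"a": A, "g": G, "g_c": G_c, "g_o": G_o}
    terms = {}
    for label in MODEL_TERMS[model]:
        if supplied[label] is None:
            raise ConfigError(f"model {model} requires the {label!r} matrix")
        terms[label] = supplied[label]
    vcm = VarianceComponentModel(phen["y"].to_numpy(), terms,
                                 weights=phen["weight"].to_numpy(),
                                 ids=list(phen["id"]))
    res = vcm.fit(**fit_kw)
    return ModelResult(trait=trait, model=model, results=res,
                       vr=res.variance_ratio(), chromosome=chromosome)


@dataclass
class ChromosomePartition:
    """Per-chromosome genomic variances from repeated model-4 fits."""

    table: pd.DataFrame          # chromosome, length_mb, variance, se, converged
    model3: ModelResult          # whole-genome reference fit
    trait: str = "trait"
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        """Sum of per-chromosome genomic variances."""
        return float(self.table["variance"].sum())

    @property
    def reference_genomic_variance(self) -> float:
        return float(self.model3.params["g"])

    @property
    def sum_ratio(self) -> float:
        """Sum of chromosomal variances over the model-3 genomic variance."""
        return self.total / self.reference_genomic_variance


def chromosome_scan(phen: pd.DataFrame, geno: GenotypeMatrix,
                    A: RelationshipMatrix, trait: str = "trait",
                    model3: Optional[ModelResult] = None,
                    shared_denominator: bool = False, **fit_kw) -> ChromosomePartition:
    """Model-4 scan over all chromosomes plus the model-3 reference fit.

    For each chromosome ``c`` the genome is split into ``G_c`` (markers on
    c) and ``G_o`` (all other markers) and model 4 is fitted; the collected
    per-chromosome variances are summed and compared with the genomic
    variance of a whole-genome model-3 fit. Chromosome length is the Mb span
    between the first and last marker. Non-convergent chromosomes are kept
    with a flag rather than aborting the scan.
    """
    phen = _check_phen(phen)
    chroms = list(geno.chromosomes())
    if len(chroms) < 2:
        raise InputError("chromosome scan needs at least 2 chromosomes")
    if model3 is None:
        G = build_G(geno)
        model3 = fit_model(phen, 3, A=A, G=G, trait=trait, **fit_kw)
    rows = []
    for c in chroms:
        on = geno.chrom == c
        length_mb = (geno.pos[on].max() - geno.pos[on].min()) / 1e6
        G_c, G_o = split_G_by_chromosome(geno, c, shared_denominator=shared_denominator)
        mr = fit_model(phen, 4, A=A, G_c=G_c, G_o=G_o, trait=trait,
                       chromosome=c, **fit_kw)
        rows.append({"chromosome": c, "length_mb": length_mb,
                     "variance": float(mr.params["g_c"]),
                     "se": float(mr.results.bse["g_c"]),
                     "converged": mr.results.converged})
    table = pd.DataFrame(rows)
    return ChromosomePartition(table=table, model3=model3, trait=trait)


# ---- summary arithmetic --------------------------------------------------

def genomic_share(sigma_g2: float, sigma_a2: float) -> float:
    """Proportion of model-3 total genetic variance attributed to markers."""
    if sigma_g2 < 0 or sigma_a2 < 0:
        raise InputError("variances must be >= 0")
    total = sigma_g2 + sigma_a2
    if total <= 0:
        raise InputError("total genetic variance is zero")
    return sigma_g2 / total


def model_total_ratio(model3: ModelResult, model1: ModelResult) -> float:
    """Model-3 total genetic variance over the model-1 (animal model) estimate."""
    if model3.model != 3 or model1.model != 1:
        raise InputError("arguments must be a model-3 and a model-1 result, in that order")
    if model3.trait != model1.trait:
        raise InputError(f"trait mismatch: {model3.trait!r} vs {model1.trait!r}")
    total3 = float(model3.params["g"] + model3.params["a"])
    return total3 / float(model1.params["a"])


def regress_variance_on_length(part: ChromosomePartition):
    """OLS of per-chromosome variance on chromosome length in Mb.

    Returns ``(slope, intercept, r_squared)``. A weak fit indicates QTL are
    not spread evenly along the genome (e.g. a major gene on one chromosome).
    """
    t = part.table
    if len(t) < 3:
        raise InputError("need at least 3 chromosomes for the regression")
    x = t["length_mb"].to_numpy(dtype=float)
    y = t["variance"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegeneracyError("chromosome lengths are all equal; regression degenerate")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def summarize_reference(ref: pd.DataFrame) -> dict:
    """Headline ratios from a table of per-trait model 1-4 components.

    Expects the column layout of
    :data:`gvarpart.reference.REFERENCE_ESTIMATES`. Returns per-trait and
    averaged genomic shares, model-3/model-1 total ratios, model-2/model-1
    ratios, and sum-of-chromosome ratios — all as proportions.
    """
    shares = {t: genomic_share(r["m3_sigma_g2"], r["m3_sigma_a2"])
              for t, r in ref.iterrows()}
    totals = {t: (r["m3_sigma_g2"] + r["m3_sigma_a2"]) / r["m1_sigma_a2"]
              for t, r in ref.iterrows()}
    m2_m1 = {t: r["m2_sigma_g2"] / r["m1_sigma_a2"] for t, r in ref.iterrows()}
    chrom_sum = {t: r["m4_sum_sigma_c2"] / r["m3_sigma_g2"] for t, r in ref.iterrows()}
    return {
        "genomic_share": shares,
        "genomic_share_avg": float(np.mean(list(shares.values()))),
        "model3_vs_model1": totals,
        "model3_vs_model1_avg": float(np.mean(list(totals.values()))),
        "model2_vs_model1": m2_m1,
        "chromosome_sum_vs_model3": chrom_sum,
    }
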