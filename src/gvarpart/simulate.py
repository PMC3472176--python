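"""Synthetic dairy-cattle data with the structure the pipeline assumes.

The generator emulates a progeny-tested bull population: a multi-generation,
sire-heavy pedigree; 29 autosomes of biallelic SNPs gene-dropped through the
pedigree with recombination; an additive QTL architecture split between
marker-tagged loci and hidden loci (the latter create a genuine residual
polygenic component that pedigree relationships, but not markers, can trace);
and deregressed-proof-like phenotypes

    y_i = mu + TBV_i + e_i,      e_i ~ N(0, sigma_e^2 / w_i)

whose residual variance shrinks with an effective-record weight ``w_i``
emulating progeny-group means of varying size.

Recombination uses the Haldane map: a gamete's source haplotype switches
between adjacent markers with probability ``(1 - exp(-2 d)) / 2`` for map
distance ``d`` Morgans, the exact marker-level law of a Poisson crossover
process with mean ``L`` crossovers per chromosome of length ``L``.

All draws are reproducible: each stage derives its generator from
``(cfg.seed, stage)`` so re-running any stage with the same config is
bit-for-bit identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, PedigreeError
from .grm import GenotypeMatrix
from .pedigree import MISSING, Pedigree

__all__ = [
    "SimConfig", "TrueValues", "simulate_pedigree", "simulate_genotypes",
    "assign_qtl_and_tbv", "simulate_drp", "simulate_dataset", "SimulatedData",
]

_BP_PER_MORGAN = 100_000_000  # 1 cM ~ 1 Mb, the usual cattle rule of thumb


@dataclass
class SimConfig:
    """Parameters of the simulated breeding population.

    Defaults describe a small progeny-testing scheme: 29 autosomes of 1 Morgan,
    founder minor allele frequencies uniform on (0.05, 0.5), 10% of QTL hidden
    from the marker panel, and effective-record weights uniform on (20, 200)
    emulating large but heterogeneous progeny groups.
    """

    n_founders: int = 100
    n_generations: int = 3
    sires_per_generation: int = 15
    offspring_per_sire: int = 20
    dam_policy: str = "unknown"  # 'unknown' or 'founder'

    n_chromosomes: int = 29
    markers_per_chromosome: Union[int, Sequence[int]] = 180
    chromosome_length_morgans: Union[float, Sequence[float]] = 1.0
    maf_low: float = 0.05
    maf_high: float = 0.5

    n_qtl: int = 2000
    qtl_hidden_fraction: float = 0.10
    qtl_chromosomes: Optional[Sequence[int]] = None  # restrict QTL to these chromosomes
    phenotype_cohort: str = "final"  # 'final' generation only, or 'all' individuals
    var_genomic: float = 100.0      # marker-tagged additive variance target
    var_polygenic: float = 25.0     # hidden-locus (residual polygenic) variance target
    var_residual: float = 25.0      # sigma_e^2 at weight 1
    mu: float = 100.0
    weight_low: float = 20.0
    weight_high: float = 200.0

    seed: int = 0

    def marker_counts(self) -> np.ndarray:
        m = self.markers_per_chromosome
        if np.isscalar(m):
            arr = np.full(self.n_chromosomes, int(m))
        else:
            arr = np.asarray(m, dtype=int)
            if arr.shape != (self.n_chromosomes,):
                raise ConfigError("markers_per_chromosome list must have n_chromosomes entries")
        if np.any(arr < 1):
            raise ConfigError("markers_per_chromosome must be >= 1")
        return arr

    def chrom_lengths(self) -> np.ndarray:
        L = self.chromosome_length_morgans
        if np.isscalar(L):
            arr = np.full(self.n_chromosomes, float(L))
        else:
            arr = np.asarray(L, dtype=float)
            if arr.shape != (self.n_chromosomes,):
                raise ConfigError("chromosome_length_morgans list must have n_chromosomes entries")
        if np.any(arr < 0):
            raise ConfigError("chromosome lengths must be >= 0")
        return arr

    def validate(self) -> None:
        counts = dict(n_founders=self.n_founders, n_chromosomes=self.n_chromosomes)
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        self.marker_counts()
        if self.n_generations < 0:
            raise ConfigError("n_generations must be >= 0")
        if self.n_generations > 0:
            if self.sires_per_generation < 1 or self.offspring_per_sire < 1:
                raise ConfigError("sires_per_generation and offspring_per_sire must be >= 1")
            if self.sires_per_generation > self.n_founders // 2:
                raise ConfigError("not enough male founders to supply the first sire set")
        if self.dam_policy not in ("unknown", "founder"):
            raise ConfigError(f"dam_policy must be 'unknown' or 'founder', got {self.dam_policy!r}")
        if self.phenotype_cohort not in ("final", "all"):
            raise ConfigError(f"phenotype_cohort must be 'final' or 'all', got {self.phenotype_cohort!r}")
        for name in ("var_genomic", "var_polygenic", "var_residual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError("founder MAF bounds must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.qtl_hidden_fraction <= 1.0):
            raise ConfigError("qtl_hidden_fraction must be in [0, 1]")
        if self.qtl_chromosomes is not None:
            bad = [c for c in self.qtl_chromosomes
                   if not (1 <= c <= self.n_chromosomes)]
            if bad:
                raise ConfigError(f"qtl_chromosomes outside 1..{self.n_chromosomes}: {bad}")
        if self.weight_low <= 0 or self.weight_high < self.weight_low:
            raise ConfigError("weight bounds must satisfy 0 < low <= high")
        self.chrom_lengths()


@dataclass
class TrueValues:
    """True breeding values and the QTL architecture behind them.

    ``tbv = tbv_genomic + tbv_polygenic``: the marker-tagged component and the
    hidden-locus component, each centered on the founder expectation and
    rescaled so its realized variance among final-generation individuals hits
    the configured target exactly.
    """

    ids: list
    tbv: np.ndarray
    tbv_genomic: np.ndarray
    tbv_polygenic: np.ndarray
    qtl: pd.DataFrame  # columns: locus, chrom, pos, effect, hidden
    generation: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "tbv": self.tbv,
                             "tbv_genomic": self.tbv_genomic,
                             "tbv_polygenic": self.tbv_polygenic})


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(cfg.seed), stage)))


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Sire-heavy multi-generation pedigree.

    Founders alternate male/female. Each later generation draws
    ``sires_per_generation`` sires at random from the previous generation's
    males; every sire gets ``offspring_per_sire`` offspring whose dam is
    either unknown or a random founder female (``dam_policy``). Offspring sex
    alternates within each sire family so sires are always available.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    ids = list(range(1, cfg.n_founders + 1))
    sire = [MISSING] * cfg.n_founders
    dam = [MISSING] * cfg.n_founders
    sex = ["M" if i % 2 == 0 else "F" for i in range(cfg.n_founders)]
    generation = [0] * cfg.n_founders
    founder_females = [i for i in range(cfg.n_founders) if sex[i] == "F"]

    prev_males = [i for i in range(cfg.n_founders) if sex[i] == "M"]
    next_id = cfg.n_founders + 1
    for g in range(1, cfg.n_generations + 1):
        if len(prev_males) < cfg.sires_per_generation:
            raise PedigreeError(f"generation {g - 1} has too few males to select sires")
        sires = rng.choice(prev_males, size=cfg.sires_per_generation, replace=False)
        cur = []
        for s in sires:
            for k in range(cfg.offspring_per_sire):
                ids.append(next_id)
                sire.append(int(s))
                if cfg.dam_policy == "founder":
                    dam.append(int(rng.choice(founder_females)))
                else:
                    dam.append(MISSING)
                sex.append("M" if k % 2 == 0 else "F")
                generation.append(g)
                cur.append(len(ids) - 1)
                next_id += 1
        prev_males = [i for i in cur if sex[i] == "M"]

    ped = Pedigree(ids=ids, sire_idx=np.array(sire), dam_idx=np.array(dam),
                   sex=np.array(sex, dtype=object))
    ped.meta["generation"] = np.array(generation)
    ped.meta["seed"] = cfg.seed
    return ped


def _marker_positions(cfg: SimConfig):
    """Genetic (Morgan) and physical (bp) positions, evenly spaced per chromosome."""
    lengths = cfg.chrom_lengths()
    gpos, bp = [], []
    for L, m_c in zip(lengths, cfg.marker_counts()):
        g = (np.arange(1, m_c + 1) / (m_c + 1)) * L
        gpos.append(g)
        if L > 0:
            bp.append(np.round(g * _BP_PER_MORGAN).astype(np.int64))
        else:
            bp.append(np.arange(1, m_c + 1, dtype=np.int64))
    return gpos, bp


def _gene_drop(ped: Pedigree, gpos: Sequence[np.ndarray], freqs: Sequence[np.ndarray],
               rng: np.random.Generator, generation: np.ndarray):
    """Drop haplotypes through the pedigree, one chromosome at a time.

    Unknown parents contribute a fresh founder-population gamete (alleles
    Bernoulli(p_j), no within-gamete structure needed because it is a single
    draw from the base population). Returns the (n, m_total) code matrix.
    """
    n = ped.n
    blocks = []
    gens = np.unique(generation)
    for g_chrom, p in zip(gpos, freqs):
        m = p.size
        if m == 0:
            continue
        hap = np.zeros((n, 2, m), dtype=np.uint8)
        d = np.diff(g_chrom, prepend=g_chrom[0])
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        r[0] = 0.5  # start haplotype uniform
        for g in gens:
            members = np.flatnonzero(generation == g)
            founders_mask = (ped.sire_idx[members] == MISSING) & (ped.dam_idx[members] == MISSING)
            fd = members[founders_mask]
            if fd.size:
                hap[fd] = (rng.random((fd.size, 2, m)) < p).astype(np.uint8)
            kids = members[~founders_mask]
            if kids.size == 0:
                continue
            for which, parent_idx in ((0, ped.sire_idx[kids]), (1, ped.dam_idx[kids])):
                known = parent_idx != MISSING
                gam = np.zeros((kids.size, m), dtype=np.uint8)
                if known.any():
                    pk = parent_idx[known]
                    switches = rng.random((int(known.sum()), m)) < r
                    source = np.cumsum(switches, axis=1) % 2
                    gam[known] = np.where(source == 0, hap[pk, 0, :], hap[pk, 1, :])
                if (~known).any():
                    gam[~known] = (rng.random((int((~known).sum()), m)) < p).astype(np.uint8)
                hap[kids, which, :] = gam
        blocks.append(hap[:, 0, :].astype(np.int16) + hap[:, 1, :])
    return np.concatenate(blocks, axis=1)


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop the marker panel through ``ped``.

    Founder haplotype alleles are Bernoulli(p_j) under Hardy-Weinberg, with
    the second-allele frequency p_j drawn from the founder MAF distribution
    and randomly oriented (so the second allele may be the major one).
    """
    cfg.validate()
    if "generation" not in ped.meta:
        raise PedigreeError("pedigree lacks generation metadata; use simulate_pedigree")
    rng = _rng(cfg, 1)
    counts = cfg.marker_counts()
    gpos, bp = _marker_positions(cfg)
    freqs = []
    for m_c in counts:
        maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=m_c)
        flip = rng.random(m_c) < 0.5
        freqs.append(np.where(flip, 1.0 - maf, maf))
    codes = _gene_drop(ped, gpos, freqs, rng, ped.meta["generation"])
    chrom = np.repeat(np.arange(1, cfg.n_chromosomes + 1), counts)
    pos = np.concatenate(bp)
    marker_ids = [f"snp{c + 1}_{j + 1}" for c in range(cfg.n_chromosomes)
                  for j in range(counts[c])]
    return GenotypeMatrix(list(ped.ids), marker_ids, chrom, pos,
                          codes.astype(float),
                          meta={"seed": cfg.seed, "founder_freqs": np.concatenate(freqs)})


def _scale_component(values: np.ndarray, final_mask: np.ndarray, target: float,
                     label: str) -> np.ndarray:
    v = float(np.var(values[final_mask], ddof=1))
    if target == 0:
        return np.zeros_like(values)
    if v <= 0:
        raise ConfigError(f"{label} TBV component has zero realized variance; "
                          "cannot rescale to a positive target")
    return values * np.sqrt(target / v)


def assign_qtl_and_tbv(geno: GenotypeMatrix, cfg: SimConfig, ped: Pedigree) -> TrueValues:
    """Sample the QTL architecture and compute true breeding values.

    A fraction ``qtl_hidden_fraction`` of the ``n_qtl`` loci is hidden: those
    loci are gene-dropped through the same pedigree but excluded from the
    marker panel, creating additive variance that markers cannot tag. Effects
    are i.i.d. normal, then each component is centered on its founder
    expectation and rescaled so its realized variance among final-generation
    individuals equals the configured target exactly.
    """
    cfg.validate()
    total_target = cfg.var_genomic + cfg.var_polygenic
    if cfg.n_qtl == 0:
        if total_target > 0:
            raise ConfigError("n_qtl=0 with a positive target genetic variance")
        z = np.zeros(geno.n)
        return TrueValues(list(geno.ids), z, z.copy(), z.copy(),
                          pd.DataFrame(columns=["locus", "chrom", "pos", "effect", "hidden"]),
                          generation=ped.meta.get("generation"))
    rng = _rng(cfg, 2)
    generation = ped.meta["generation"]
    final_mask = generation == generation.max()
    n_hidden = int(round(cfg.qtl_hidden_fraction * cfg.n_qtl)) if cfg.var_polygenic > 0 else 0
    n_tagged = cfg.n_qtl - n_hidden
    if cfg.var_genomic > 0 and n_tagged == 0:
        raise ConfigError("no marker-tagged QTL left but var_genomic > 0")
    if n_tagged > geno.m:
        raise ConfigError(f"n_qtl ({n_tagged} tagged) exceeds marker count {geno.m}")

    rows = []
    founder_mask = ped.is_founder()
    # -- marker-tagged component
    if cfg.qtl_chromosomes is not None:
        candidates = np.flatnonzero(np.isin(geno.chrom, list(cfg.qtl_chromosomes)))
    else:
        candidates = np.arange(geno.m)
    if n_tagged > candidates.size:
        raise ConfigError(f"{n_tagged} tagged QTL exceed the {candidates.size} "
                          "eligible markers")
    tbv_g = np.zeros(geno.n)
    if n_tagged > 0 and cfg.var_genomic > 0:
        idx = np.sort(rng.choice(candidates, size=n_tagged, replace=False))
        effects = rng.standard_normal(n_tagged)
        raw = geno.codes[:, idx] @ effects
        raw = raw - raw[founder_mask].mean()
        tbv_g = _scale_component(raw, final_mask, cfg.var_genomic, "marker-tagged")
        scale = tbv_g[final_mask].std(ddof=1) / raw[final_mask].std(ddof=1)
        for k, j in enumerate(idx):
            rows.append((geno.marker_ids[j], geno.chrom[j], geno.pos[j],
                         effects[k] * scale, False))

    # -- hidden-locus component, gene-dropped through the same pedigree
    tbv_p = np.zeros(geno.n)
    if n_hidden > 0 and cfg.var_polygenic > 0:
        lengths = cfg.chrom_lengths()
        if cfg.qtl_chromosomes is not None:
            pool = np.asarray(list(cfg.qtl_chromosomes), dtype=int) - 1
            chrom_of = rng.choice(pool, size=n_hidden)
        else:
            chrom_of = rng.integers(0, cfg.n_chromosomes, size=n_hidden)
        gpos, freqs = [], []
        for c in range(cfg.n_chromosomes):
            k = int((chrom_of == c).sum())
            gpos.append(np.sort(rng.uniform(0, max(lengths[c], 1e-9), size=k)))
            maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=k)
            flip = rng.random(k) < 0.5
            freqs.append(np.where(flip, 1.0 - maf, maf))
        hidden_codes = _gene_drop(ped, gpos, freqs, rng, generation)
        effects = rng.standard_normal(n_hidden)
        raw = hidden_codes @ effects
        raw = raw - raw[founder_mask].mean()
        tbv_p = _scale_component(raw, final_mask, cfg.var_polygenic, "hidden-locus")
        scale = tbv_p[final_mask].std(ddof=1) / raw[final_mask].std(ddof=1)
        j = 0
        for c in range(cfg.n_chromosomes):
            for g in gpos[c]:
                rows.append((f"hidden{j + 1}", c + 1, int(g * _BP_PER_MORGAN),
                             effects[j] * scale, True))
                j += 1

    qtl = pd.DataFrame(rows, columns=["locus", "chrom", "pos", "effect", "hidden"])
    return TrueValues(list(geno.ids), tbv_g + tbv_p, tbv_g, tbv_p, qtl,
                      generation=generation)


def simulate_drp(tv: TrueValues, cfg: SimConfig,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Deregressed-proof-like phenotypes.

    Each phenotyped individual gets an effective-record weight ``w_i``
    uniform on the configured bounds and a record ``y_i = mu + TBV_i + e_i``
    with ``e_i ~ N(0, sigma_e^2 / w_i)``. With ``phenotype_cohort='final'``
    (the default) only the final-generation cohort is phenotyped — the
    analog of the genotyped, progeny-tested bull cohort, for which the
    variance targets are defined; ancestors then contribute pedigree
    structure only. Returns a tidy table (id, trait, y, weight).
    """
    cfg.validate()
    if cfg.var_residual <= 0:
        raise ConfigError("var_residual must be > 0 for finite-weight records")
    if rng is None:
        rng = _rng(cfg, 3)
    if cfg.phenotype_cohort == "final" and tv.generation is not None:
        mask = tv.generation == tv.generation.max()
    else:
        mask = np.ones(len(tv.ids), dtype=bool)
    ids = [tv.ids[i] for i in np.flatnonzero(mask)]
    n = len(ids)
    w = rng.uniform(cfg.weight_low, cfg.weight_high, size=n)
    e = rng.standard_normal(n) * np.sqrt(cfg.var_residual / w)
    return pd.DataFrame({"id": ids, "trait": "sim",
                         "y": cfg.mu + tv.tbv[mask] + e, "weight": w})


@dataclass
class SimulatedData:
    """Bundle of one complete simulated dataset."""

    cfg: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    truth: TrueValues
    phenotypes: pd.DataFrame


def simulate_dataset(cfg: Optional[SimConfig] = None, **overrides) -> SimulatedData:
    """Run all four stages under one config and return the bundle."""
    if cfg is None:
        cfg = SimConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    truth = assign_qtl_and_tbv(geno, cfg, ped)
    phen = simulate_drp(truth, cfg)
    return SimulatedData(cfg, ped, geno, truth, phen)
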