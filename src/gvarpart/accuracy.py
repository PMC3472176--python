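"""How much additive variance can a marker panel of a given size explain?

The idea: treat one random half of a 2N-marker sample as stand-in causal
loci and build the "true" relationship matrix G_t from them; build the
observed matrix G_m from the other half; then regress the elements of G_t
on those of G_m,

    g_t[jk] = alpha + beta * g_m[jk] + e,   j <= k,

after subtracting 1 from both diagonals to remove their dominance. The slope
beta estimates the expected proportion of additive genetic variance a panel
of N markers can explain; repeating over N traces an empirical beta(N)
curve. An unbiased stand-in for G_t at panel size N is then

    G* = beta * (G_m - I) + I,

which rescales off-diagonal structure (and hence inflates a genomic variance
estimated with G_m by roughly 1/beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneracyError, InputError, SamplingError
from .grm import GenotypeMatrix, build_G
from .relmatrix import RelationshipMatrix

__all__ = ["BetaCurve", "sample_split_markers", "estimate_beta", "beta_curve",
           "adjust_G"]


def sample_split_markers(geno: GenotypeMatrix, N: int, seed) -> tuple:
    """Sample 2N distinct markers genome-wide and split them into two panels.

    Returns ``(panel1, panel2)`` as two disjoint :class:`GenotypeMatrix`
    views of N markers each; reproducible for a fixed seed.
    """
    if N < 1:
        raise SamplingError("N must be >= 1")
    if 2 * N > geno.m:
        raise SamplingError(f"2N = {2 * N} exceeds the {geno.m} available markers")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(geno.m, size=2 * N, replace=False)
    rng.shuffle(chosen)
    first = np.sort(chosen[:N])
    second = np.sort(chosen[N:])
    return geno.select_markers(first), geno.select_markers(second)


def _paired_elements(G_m: RelationshipMatrix, G_t: RelationshipMatrix,
                     off_diagonal_only: bool = False):
    if G_m.ids != G_t.ids:
        raise InputError("matrices must cover the same individuals in the same order")
    n = G_m.n
    a = G_m.values - np.eye(n)  # remove diagonal dominance
    b = G_t.values - np.eye(n)
    i, j = np.triu_indices(n, k=1 if off_diagonal_only else 0)
    return a[i, j], b[i, j]


def estimate_beta(G_m: RelationshipMatrix, G_t: RelationshipMatrix,
                  off_diagonal_only: bool = False) -> tuple:
    """OLS of G_t elements on G_m elements over all pairs j <= k.

    Both diagonals have 1.0 subtracted first. Returns ``(alpha, beta)``.
    ``off_diagonal_only`` drops the (shifted) diagonal as a sensitivity
    variant.
    """
    x, y = _paired_elements(G_m, G_t, off_diagonal_only)
    if np.ptp(x) == 0:
        raise DegeneracyError("G_m elements have zero variance; beta undefined")
    fit = stats.linregress(x, y)
    return float(fit.intercept), float(fit.slope)


@dataclass
class BetaCurve:
    """beta as an empirical function of panel size N."""

    replicates: pd.DataFrame   # N, replicate, alpha, beta
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        g = self.replicates.groupby("N")["beta"]
        out = pd.DataFrame({"beta_mean": g.mean(), "beta_sd": g.std()})
        return out.reset_index()

    def plot(self, ax=None):
        """Mean beta against N with +/- 1 SD whiskers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary
        ax.errorbar(s["N"], s["beta_mean"], yerr=s["beta_sd"].fillna(0.0),
                    marker="o", capsize=3)
        ax.set_xlabel("number of markers N")
        ax.set_ylabel(r"expected proportion explained ($\beta$)")
        ax.set_ylim(0, 1.05)
        return ax


def beta_curve(geno: GenotypeMatrix, N_values: Sequence[int],
               n_replicates: int = 10, seed: int = 0,
               off_diagonal_only: bool = False) -> BetaCurve:
    """Estimate beta for each panel size over seeded replicates.

    For each N and replicate: sample and split 2N markers, build G_m from
    panel 1 and G_t from panel 2 (each centered by its own within-panel
    sample frequencies), regress, and record (alpha, beta).
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    rows = []
    ss = np.random.SeedSequence(seed)
    for N in N_values:
        for rep in range(n_replicates):
            child = np.random.SeedSequence((int(seed), int(N), rep))
            p1, p2 = sample_split_markers(geno, int(N), child)
            G_m = build_G(p1)
            G_t = build_G(p2)
            alpha, beta = estimate_beta(G_m, G_t, off_diagonal_only)
            rows.append({"N": int(N), "replicate": rep, "alpha": alpha, "beta": beta})
    return BetaCurve(pd.DataFrame(rows), seed=seed,
                     meta={"n_replicates": n_replicates, "entropy": ss.entropy})


@dataclass
class AdjustedG:
    """A beta-rescaled genomic relationship matrix G* = beta (G - I) + I."""

    matrix: RelationshipMatrix
    beta: float


def adjust_G(G_m: RelationshipMatrix, beta: float) -> AdjustedG:
    """Rescale a marker GRM to an unbiased stand-in for the causal-locus GRM.

    ``beta`` is expected in (0, 1]; values outside only warn, since a
    sampling estimate can fall slightly outside.
    """
    if not (0.0 < beta <= 1.0):
        import warnings

        warnings.warn(f"beta = {beta:.4g} outside (0, 1]; G* may be ill-scaled",
                      stacklevel=2)
    n = G_m.n
    values = beta * (G_m.values - np.eye(n)) + np.eye(n)
    out = RelationshipMatrix(G_m.ids, values, kind="adjusted_Gstar",
                             meta={**G_m.meta, "beta": float(beta)})
    return AdjustedG(matrix=out, beta=float(beta))
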