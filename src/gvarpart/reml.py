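"""Restricted maximum likelihood for relationship-matrix mixed models.

The model is

    y = 1 mu + sum_r Z_r u_r + e,   u_r ~ N(0, K_r sigma_r^2),  e ~ N(0, D sigma_e^2)

with a general mean as the only fixed effect, one or more correlated random
terms whose covariance structures K_r are relationship matrices (pedigree A,
genomic G, chromosome split G_c/G_o), and a heterogeneous residual whose
diagonal D carries per-record weights: a record with effective-record weight
w_i has D_ii = 1/w_i, so its residual variance is sigma_e^2 / w_i.

Estimation maximizes the restricted likelihood

    l(theta) = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ]

(up to a constant), with V = sum_r sigma_r^2 Z_r K_r Z_r' + sigma_e^2 D and
P the REML projection, using average-information (AI) updates safeguarded by
step halving and an EM fallback; EM steps cannot decrease the restricted
likelihood, and AI steps are only accepted if they do not, so the accepted
log-likelihood trace is non-decreasing. Standard errors come from the inverse
AI matrix at convergence. Dense Cholesky algebra throughout: the intended
scale is up to a few thousand records.

The public surface follows the Model/Results convention: build a
:class:`VarianceComponentModel`, call :meth:`~VarianceComponentModel.fit`,
and read estimates, standard errors and diagnostics off the returned
:class:`REMLResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import InputError, NumericalError
from .relmatrix import RelationshipMatrix

__all__ = ["RandomTerm", "VarianceComponentModel", "REMLResults", "restricted_loglik",
           "reml_fit", "variance_ratio"]

#: relative lower bound for variance components, as a fraction of var(y)
VAR_FLOOR_FRACTION = 1e-8


@dataclass
class RandomTerm:
    """One correlated random effect.

    ``level_ids`` orders the levels of u_r (rows of K). ``record_levels``
    maps each phenotype record to a level — the incidence matrix Z_r in
    indicator form. For the usual one-record-per-individual case both are
    just the individual ids.
    """

    name: str
    K: np.ndarray
    level_ids: list
    record_levels: np.ndarray  # index into level_ids per record

    @property
    def n_levels(self) -> int:
        return self.K.shape[0]

    def zkz(self) -> np.ndarray:
        """Z K Z' as a dense (n_records, n_records) matrix."""
        return self.K[np.ix_(self.record_levels, self.record_levels)]


class VarianceComponentModel:
    """REML mixed model for a single trait with relationship-structured terms.

    Parameters
    ----------
    y
        Response vector (one record per row).
    terms
        Mapping ``name -> RelationshipMatrix`` (or raw symmetric ndarray) of
        random-term covariance structures, e.g. ``{"g": G, "a": A}``.
    weights
        Effective-record weight per record; the residual covariance is
        ``diag(1/weights) * sigma_e^2``. Defaults to 1.
    ids
        Record-to-individual ids used to align each term's matrix. Required
        when terms are RelationshipMatrix objects whose order may differ from
        the records'. With raw ndarrays, matrices must already be aligned.

    Examples
    --------
    >>> model = VarianceComponentModel(y, {"g": G}, weights=w, ids=ids)
    >>> res = model.fit()
    >>> res.params["g"], res.bse["g"], res.llf
    """

    def __init__(self, y, terms, weights=None, ids: Optional[Sequence] = None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.size
        if n < 2:
            raise InputError("need at least 2 records")
        if weights is None:
            weights = np.ones(n)
        self.weights = np.asarray(weights, dtype=float).ravel()
        if self.weights.shape != (n,):
            raise InputError("weights length does not match y")
        if np.any(self.weights <= 0):
            raise InputError("all effective-record weights must be > 0")
        self.ids = list(ids) if ids is not None else list(range(n))
        if len(self.ids) != n:
            raise InputError("ids length does not match y")
        self.n = n

        self.terms: list[RandomTerm] = []
        items = terms.items() if isinstance(terms, dict) else terms
        for name, K in items:
            self.terms.append(self._make_term(name, K))
        if not self.terms:
            raise InputError("at least one random term is required")
        self.term_names = [t.name for t in self.terms]
        if len(set(self.term_names)) != len(self.term_names):
            raise InputError("duplicate random-term names")
        self.param_names = self.term_names + ["residual"]
        self.D = 1.0 / self.weights
        self.X = np.ones((n, 1))
        self._zkz = [t.zkz() for t in self.terms]
        if self.n < len(self.param_names) + 1:
            raise InputError("fewer records than variance parameters + 1")
        # REML works on error contrasts: project everything onto the
        # orthogonal complement of X once. This removes X's direction from
        # V — important because a sample-centered G has the ones vector as
        # an exact null direction, which would otherwise make V nearly
        # singular whenever the residual variance approaches its floor.
        Q, _ = np.linalg.qr(self.X, mode="complete")
        L = Q[:, 1:]
        self._structs = [L.T @ S @ L for S in self._zkz]
        self._structs.append(L.T @ (self.D[:, None] * L))
        self._yt = L.T @ self.y

    def _make_term(self, name, K) -> RandomTerm:
        if isinstance(K, RelationshipMatrix):
            pos = {ind: i for i, ind in enumerate(K.ids)}
            try:
                rec = np.array([pos[i] for i in self.ids], dtype=int)
            except KeyError as exc:
                raise InputError(
                    f"record id {exc.args[0]!r} missing from matrix of term {name!r}") from None
            return RandomTerm(name, K.values, list(K.ids), rec)
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise InputError(f"covariance of term {name!r} must be square")
        if K.shape[0] == self.n:
            rec = np.arange(self.n)
            return RandomTerm(name, K, list(self.ids), rec)
        raise InputError(
            f"covariance of term {name!r} has dimension {K.shape[0]} != {self.n} records; "
            "pass a RelationshipMatrix with ids to align")

    # ---- likelihood machinery -------------------------------------------

    def _variances(self, variances) -> np.ndarray:
        v = np.asarray(variances, dtype=float).ravel()
        if v.shape != (len(self.param_names),):
            raise InputError(f"expected {len(self.param_names)} variances "
                             f"({', '.join(self.param_names)})")
        if np.any(v < 0):
            raise InputError("variances must be >= 0")
        return v

    def _projection(self, v: np.ndarray):
        """Return (llf, P, Py) in the contrast space for the variance vector v.

        With L an orthonormal basis of the complement of X, the restricted
        log-likelihood is -1/2 [ log|L'VL| + y'L (L'VL)^-1 L'y ], equal to
        the familiar -1/2 [ log|V| + log|X'V^-1 X| + y'Py ] up to a constant,
        and P is simply (L'VL)^-1 in this space.
        """
        V = sum(s2 * S for s2, S in zip(v, self._structs))
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            cond = np.linalg.cond(V)
            raise NumericalError(f"V is singular or indefinite (cond={cond:.3g})") from exc
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        P = linalg.cho_solve((c, low), np.eye(self.n - 1), check_finite=False)
        Py = P @ self._yt
        yPy = float(self._yt @ Py)
        llf = -0.5 * (logdetV + yPy)
        return llf, P, Py

    def loglike(self, variances) -> float:
        """Restricted log-likelihood at the given variances, up to the REML constant."""
        v = self._variances(variances)
        return self._projection(v)[0]

    def _score_ai(self, P: np.ndarray, Py: np.ndarray):
        """Score vector and average-information matrix at the current point."""
        k = len(self.param_names)
        f = [S @ Py for S in self._structs]  # V_r P y in contrast space
        score = np.empty(k)
        for r, S in enumerate(self._structs):
            trPS = float(np.sum(P * S))  # tr(P S) via symmetry
            score[r] = -0.5 * (trPS - float(Py @ f[r]))
        F = np.column_stack(f)
        AI = 0.5 * (F.T @ P @ F)
        return score, AI

    def _em_step(self, v: np.ndarray, P: np.ndarray, Py: np.ndarray) -> np.ndarray:
        """EM update; an ascent step for every component."""
        k = len(self.param_names)
        qs = [t.n_levels for t in self.terms] + [self.n]
        new = np.empty(k)
        for r, (S, q) in enumerate(zip(self._structs, qs)):
            trPS = float(np.sum(P * S))
            yPSPy = float(Py @ (S @ Py))
            new[r] = v[r] + (v[r] ** 2 / q) * (yPSPy - trPS)
        return new

    def fit(self, start=None, tol: float = 1e-8, param_tol: float = 1e-6,
            maxiter: int = 200) -> "REMLResults":
        """AI-REML with step halving and EM fallback.

        ``start`` defaults to an equal split of var(y) over all components.
        Convergence requires both a relative log-likelihood change below
        ``tol`` and a maximum relative parameter change below ``param_tol``.
        Non-convergence returns the best iterate with ``converged=False``.
        """
        k = len(self.param_names)
        vary = float(np.var(self.y, ddof=1))
        if vary <= 0:
            raise InputError("response has zero variance")
        floor = VAR_FLOOR_FRACTION * vary
        if start is None:
            v = np.full(k, vary / k)
        else:
            v = np.maximum(self._variances(start), floor)

        llf, P, Py = self._projection(v)
        history = [(0, llf, v.copy(), "init")]
        converged = False
        n_iter = 0
        for it in range(1, maxiter + 1):
            n_iter = it
            score, AI = self._score_ai(P, Py)
            # active-set handling: a component sitting on the floor whose
            # score pushes it further down is pinned there for this step,
            # which avoids the slow EM crawl toward a zero estimate
            pinned = (v <= floor * (1.0 + 1e-9)) & (score < 0)
            free = ~pinned
            v_pin = v.copy()
            v_pin[pinned] = floor
            step_kind = "ai"
            delta = None
            if free.any():
                try:
                    d_free = linalg.solve(AI[np.ix_(free, free)], score[free],
                                          assume_a="sym")
                    if np.all(np.isfinite(d_free)):
                        delta = np.zeros(k)
                        delta[free] = d_free
                except linalg.LinAlgError:
                    pass

            accepted = None
            if delta is not None:
                frac = 1.0
                for _ in range(12):
                    cand = np.maximum(v_pin + frac * delta, floor)
                    try:
                        cllf, cP, cPy = self._projection(cand)
                    except NumericalError:
                        cllf = -np.inf
                    if cllf >= llf - 1e-10:
                        accepted = (cand, cllf, cP, cPy)
                        break
                    frac *= 0.5
                    step_kind = "ai-halved"
            if accepted is None:
                cand = np.maximum(self._em_step(v_pin, P, Py), floor)
                cand[pinned] = floor
                cllf, cP, cPy = self._projection(cand)
                step_kind = "em"
                accepted = (cand, cllf, cP, cPy)

            new_v, new_llf, P, Py = accepted
            rel_l = abs(new_llf - llf) / max(1.0, abs(llf))
            rel_p = float(np.max(np.abs(new_v - v) / np.maximum(np.abs(v), floor)))
            v, llf = new_v, new_llf
            history.append((it, llf, v.copy(), step_kind))
            if rel_l < tol and rel_p < param_tol:
                converged = True
                break

        _, AI = self._score_ai(P, Py)
        bse = np.full(k, np.nan)
        try:
            AIinv = linalg.inv(AI)
            d = np.diag(AIinv)
            bse = np.sqrt(np.where(d > 0, d, np.nan))
        except linalg.LinAlgError:
            pass
        at_boundary = v <= floor * (1.0 + 1e-6)
        return REMLResults(model=self, params=pd.Series(v, index=self.param_names),
                           bse=pd.Series(bse, index=self.param_names), llf=llf,
                           converged=converged, n_iter=n_iter, history=history,
                           at_boundary=pd.Series(at_boundary, index=self.param_names))


@dataclass
class REMLResults:
    """Converged (or best-effort) REML estimates and diagnostics."""

    model: VarianceComponentModel
    params: pd.Series      # variance estimates, index = term names + 'residual'
    bse: pd.Series         # asymptotic SEs from the inverse AI matrix
    llf: float             # restricted log-likelihood (up to constant)
    converged: bool
    n_iter: int
    history: list          # (iteration, llf, params, step kind)
    at_boundary: pd.Series = field(default=None)

    @property
    def genetic_variance(self) -> float:
        """Sum of all non-residual variance components."""
        return float(self.params.drop("residual").sum())

    def variance_ratio(self, mean_weight_diag: Optional[float] = None) -> float:
        """Genetic variance over total variance at the average record weight.

        VR = sum_r sigma_r^2 / (sum_r sigma_r^2 + dbar * sigma_e^2) with
        ``dbar`` the arithmetic mean diagonal of D (default: from the model's
        weights). This is the heritability of the weighted records — for
        deregressed proofs, the reliability-dependent heritability of the
        proof, not of the underlying trait.
        """
        if mean_weight_diag is None:
            mean_weight_diag = float(np.mean(self.model.D))
        sg = self.genetic_variance
        total = sg + mean_weight_diag * float(self.params["residual"])
        if total <= 0:
            raise InputError("total variance is zero; VR undefined")
        return sg / total

    def summary(self) -> str:
        lines = ["Variance component estimates (REML)",
                 "=" * 46,
                 f"records: {self.model.n}   terms: {', '.join(self.model.term_names)}",
                 f"logL: {self.llf:.6f}   iterations: {self.n_iter}   "
                 f"converged: {self.converged}",
                 "-" * 46,
                 f"{'component':<12}{'estimate':>12}{'SE':>12}  flags"]
        for name in self.params.index:
            flag = "boundary" if (self.at_boundary is not None and self.at_boundary[name]) else ""
            lines.append(f"{name:<12}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}  {flag}")
        lines.append("-" * 46)
        lines.append(f"VR (at mean weight): {self.variance_ratio():.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"component": self.params.index,
                             "estimate": self.params.values,
                             "se": self.bse.values})


# ---- functional wrappers -------------------------------------------------

def restricted_loglik(model: VarianceComponentModel, variances) -> float:
    """Restricted log-likelihood of ``model`` at ``variances`` (terms + residual)."""
    return model.loglike(variances)


def reml_fit(model: VarianceComponentModel, init=None, tol: float = 1e-8,
             max_iter: int = 200) -> REMLResults:
    """Fit ``model`` by AI-REML; see :meth:`VarianceComponentModel.fit`."""
    return model.fit(start=init, tol=tol, maxiter=max_iter)


def variance_ratio(est: Union[REMLResults, pd.Series], mean_weight_diag: float = 1.0) -> float:
    """VR from estimates and the mean residual-weight diagonal.

    Accepts a fitted :class:`REMLResults` (then ``mean_weight_diag`` may
    override the model's own mean D) or a plain Series of variances indexed
    by term names plus ``'residual'``.
    """
    if isinstance(est, REMLResults):
        return est.variance_ratio(mean_weight_diag)
    sg = float(est.drop("residual").sum())
    total = sg + mean_weight_diag * float(est["residual"])
    if total <= 0:
        raise InputError("total variance is zero; VR undefined")
    return sg / total
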