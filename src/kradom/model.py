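"""Additive + dominance animal model: REML variance components and BLUP.

The model is the classical crossbreeding animal model

    y = X b + Z a + W d + e,
    a ~ N(0, A sa2),  d ~ N(0, D sd2),  e ~ N(0, I se2),

with ``A`` the numerator relationship matrix, ``D`` the dominance
relationship matrix, fixed effects (sex, hatch date) in ``X`` and one
incidence column per animal in ``Z`` and ``W``.  Variance components are
estimated by REML — expectation-maximisation steps for stability, switching
to average-information (AI) Newton steps near the optimum, with
non-negativity enforced by projection and persistent zeros pinned at the
boundary.  BLUPs of additive and dominance effects come from Henderson's
mixed-model equations at the converged components.

Heritability is ``h2 = sa2 / (sa2 + sd2 + se2)`` and the dominance ratio is
``sd2 / sp2``; the standard error of h2 uses the delta method on the
inverse AI matrix.

The module exposes both a functional surface (:func:`build_design_matrices`,
:func:`reml_estimate`, :func:`solve_mme`, :func:`genetic_parameters`) and a
statsmodels-style pair :class:`AdditiveDominanceModel` /
:class:`AdditiveDominanceResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from ._linalg import chol_psd, inv_psd, logdet_from_chol
from .pedigree import Pedigree, RelationshipMatrix, topological_order

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "VarianceComponents",
    "MMESolution",
    "GeneticParameters",
    "build_design_matrices",
    "restricted_loglik",
    "reml_estimate",
    "solve_mme",
    "genetic_parameters",
    "AdditiveDominanceModel",
    "AdditiveDominanceResults",
    "fit_report",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response trait at one age, plus the fixed factors."""

    trait: str = "bw_g"
    age: int | None = None
    fixed_effects: tuple[str, ...] = ("sex", "hatch")


@dataclass(frozen=True)
class DesignMatrices:
    """Response and incidence matrices of one univariate animal-model fit.

    ``Z`` and ``W`` have one column per pedigree animal (animals without
    records keep all-zero columns — they still receive BLUPs through the
    relationship structure).  ``record_animal_idx`` maps each record row to
    its animal's column.
    """

    y: np.ndarray
    X: np.ndarray
    x_names: tuple[str, ...]
    animal_ids: tuple[str, ...]
    record_animal_idx: np.ndarray

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @cached_property
    def Z(self) -> np.ndarray:
        Z = np.zeros((self.n_records, self.n_animals))
        Z[np.arange(self.n_records), self.record_animal_idx] = 1.0
        return Z

    @property
    def W(self) -> np.ndarray:
        # dominance incidence: same record-to-animal assignment as Z
        return self.Z


def _dummy_code(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Reference-level dummies; level order = order of first appearance."""
    levels = list(dict.fromkeys(values))
    cols = [(values == lev).to_numpy(float) for lev in levels[1:]]
    names = [f"{values.name}[{lev}]" for lev in levels[1:]]
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(values), 0)), names


def build_design_matrices(
    pheno: pd.DataFrame, ped: Pedigree, spec: ModelSpec | None = None
) -> DesignMatrices:
    """Build y, X, Z, W from a long-format phenotype table and a pedigree.

    Rows are filtered to ``spec.age`` when given and to non-missing trait
    values.  Fixed factors use first-level reference dummy coding with an
    intercept; a rank-deficient X (confounded factors) is an error.
    """
    spec = spec or ModelSpec()
    df = pheno
    if spec.age is not None:
        df = df[df["age_wk"].astype(int) == int(spec.age)]
    df = df[pd.to_numeric(df[spec.trait], errors="coerce").notna()]
    if len(df) == 0:
        raise ValueError("no phenotype records after filtering")
    unknown = set(df["animal"].astype(str)) - set(ped.ids)
    if unknown:
        raise ValueError(
            f"phenotype records reference animals absent from the pedigree: "
            f"{sorted(unknown)[:5]}"
        )
    y = pd.to_numeric(df[spec.trait]).to_numpy(float)
    blocks = [np.ones((len(df), 1))]
    names = ["intercept"]
    for factor in spec.fixed_effects:
        if factor not in df.columns:
            raise ValueError(f"fixed-effect column {factor!r} missing from phenotypes")
        block, blocknames = _dummy_code(df[factor].astype(str).rename(factor))
        blocks.append(block)
        names.extend(blocknames)
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "fixed-effect design matrix is rank deficient; factors "
            f"{list(spec.fixed_effects)} are confounded"
        )
    rec_idx = np.array([ped.index(a) for a in df["animal"].astype(str)], dtype=np.int64)
    return DesignMatrices(
        y=y,
        X=X,
        x_names=tuple(names),
        animal_ids=ped.ids,
        record_animal_idx=rec_idx,
    )


def _v_parts(
    dm: DesignMatrices, A: RelationshipMatrix, D: RelationshipMatrix
) -> list[np.ndarray]:
    """Record-level covariance building blocks [ZAZ', WDW', I]."""
    for M, name in ((A, "A"), (D, "D")):
        if tuple(M.ids) != tuple(dm.animal_ids):
            raise ValueError(f"{name} matrix ids do not match the design matrices")
    r = dm.record_animal_idx
    ix = np.ix_(r, r)
    return [A.values[ix], D.values[ix], np.eye(dm.n_records)]


def _reml_eval(theta, y, X, parts, need_P=True):
    """Restricted log-likelihood (and optionally the projection matrix) at theta.

    With ``need_P=False`` only the Cholesky solves against ``X`` and ``y``
    are performed, which is ~3x cheaper than forming the full projector —
    used when screening candidate update steps.
    """
    V = theta[0] * parts[0] + theta[1] * parts[1] + theta[2] * parts[2]
    L, _ = chol_psd(V)
    n, p = X.shape
    Vinv_X = sla.cho_solve((L, True), X)
    Vinv_y = sla.cho_solve((L, True), y)
    XtVinvX = X.T @ Vinv_X
    Lx, _ = chol_psd(XtVinvX)
    beta = sla.cho_solve((Lx, True), X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    ll = -0.5 * (
        (n - p) * _LOG2PI
        + logdet_from_chol(L)
        + logdet_from_chol(Lx)
        + float(y @ Py)
    )
    P = None
    if need_P:
        Vinv = sla.cho_solve((L, True), np.eye(n))
        P = Vinv - Vinv_X @ sla.cho_solve((Lx, True), Vinv_X.T)
    return ll, P, Py


def restricted_loglik(
    theta: Sequence[float],
    dm: DesignMatrices,
    A: RelationshipMatrix,
    D: RelationshipMatrix,
) -> float:
    """Restricted log-likelihood at variance components ``(sa2, sd2, se2)``.

    Includes the Gaussian constant, so values are comparable across
    parameter points (and with a direct error-contrast evaluation up to the
    fixed ``log|X'X|`` convention term).
    """
    parts = _v_parts(dm, A, D)
    ll, _, _ = _reml_eval(np.asarray(theta, float), dm.y, dm.X, parts, need_P=False)
    return ll


@dataclass
class VarianceComponents:
    """REML variance components and derived genetic parameters (grams²)."""

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    se_sigma2_a: float
    se_sigma2_d: float
    se_sigma2_e: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: tuple[float, ...]

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.sigma2_p if self.sigma2_p > 0 else float("nan")

    @property
    def d_ratio(self) -> float:
        return self.sigma2_d / self.sigma2_p if self.sigma2_p > 0 else float("nan")


def reml_estimate(
    dm: DesignMatrices,
    A: RelationshipMatrix,
    D: RelationshipMatrix,
    init: Sequence[float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_em: int = 3,
    fix_zero: Sequence[str] = (),
) -> VarianceComponents:
    """Estimate ``(sa2, sd2, se2)`` by monotone EM/AI-REML.

    The first ``n_em`` iterations are pure EM (guaranteed likelihood
    ascent); afterwards an average-information Newton step is attempted
    with step halving and is accepted only if it does not decrease the
    restricted log-likelihood, falling back to EM otherwise.  Components
    are constrained non-negative by projection; a component at zero for 3
    consecutive iterations is fixed there and leaves the update set.

    Convergence requires both a relative component change below ``tol``
    and a log-likelihood change below 1e-6.  If ``max_iter`` is reached
    first, the result is returned with ``converged=False``.

    ``fix_zero`` names components (``"sigma2_a"``, ``"sigma2_d"``) to hold
    at exactly zero, e.g. to reduce the model to a purely additive one.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    y, X = dm.y, dm.X
    parts = _v_parts(dm, A, D)
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough records to estimate variance components")
    # effective number of levels per component (EM denominators)
    q = np.array([dm.n_animals, dm.n_animals, n], dtype=float)

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    vp = float(resid @ resid) / max(n - p, 1)
    if vp <= 0:
        vp = max(float(np.var(y)), 1e-12)
    theta = np.asarray(init, float).copy() if init is not None else np.full(3, vp / 3.0)
    if np.any(theta < 0):
        raise ValueError("initial variance components must be non-negative")
    theta = np.maximum(theta, 0.0)
    if theta[2] == 0:
        theta[2] = vp * 1e-6  # keep V invertible at the start
    comp_index = {"sigma2_a": 0, "sigma2_d": 1, "sigma2_e": 2}
    fixed = np.zeros(3, dtype=bool)
    for name in fix_zero:
        k = comp_index[name]
        fixed[k] = True
        theta[k] = 0.0

    ll, P, Py = _reml_eval(theta, y, X, parts)
    trace = [ll]
    pin_count = np.zeros(3, dtype=int)
    converged = False
    it = 0

    def stats(P, Py):
        tr = np.array([np.sum(P * parts[k]) for k in range(3)])
        t = [parts[k] @ Py for k in range(3)]
        quad = np.array([float(Py @ t[k]) for k in range(3)])
        return tr, quad, t

    for it in range(1, max_iter + 1):
        tr, quad, t = stats(P, Py)
        free = ~fixed
        accepted = None

        if it > n_em and free.sum() > 0:
            g = 0.5 * (quad - tr)
            idx = np.flatnonzero(free)
            AI = np.empty((len(idx), len(idx)))
            Pt = [P @ t[k] for k in idx]
            for a_, ka in enumerate(idx):
                for b_ in range(a_, len(idx)):
                    AI[a_, b_] = AI[b_, a_] = 0.5 * float(t[ka] @ Pt[b_])
            try:
                delta = np.linalg.solve(AI, g[idx])
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(5):
                    cand = theta.copy()
                    cand[idx] = np.maximum(theta[idx] + step * delta, 0.0)
                    try:
                        ll_c, _, _ = _reml_eval(cand, y, X, parts, need_P=False)
                    except np.linalg.LinAlgError:
                        ll_c = -np.inf
                    if ll_c >= ll - 1e-12:
                        accepted = cand
                        break
                    step *= 0.5

        if accepted is None:
            cand = theta.copy()
            for k in np.flatnonzero(free):
                cand[k] = max(theta[k] + theta[k] ** 2 / q[k] * (quad[k] - tr[k]), 0.0)
            ll_c, _, _ = _reml_eval(cand, y, X, parts, need_P=False)
            if ll_c < ll - 1e-10:
                # numerically stalled: no admissible ascent step remains
                converged = True
                break
            accepted = cand

        new_theta = accepted
        new_ll, P, Py = _reml_eval(new_theta, y, X, parts)
        d_theta = np.abs(new_theta - theta)
        d_ll = new_ll - ll
        theta, ll = new_theta, new_ll
        trace.append(ll)
        logger.info(
            "REML iter %d: sa2=%.6g sd2=%.6g se2=%.6g logL=%.8f", it, *theta, ll
        )

        at_zero = free & (theta <= 0.0)
        pin_count[at_zero] += 1
        pin_count[free & ~at_zero] = 0
        newly_fixed = pin_count >= 3
        fixed |= newly_fixed

        rel = float(np.max(d_theta / np.maximum(np.abs(theta), vp * 1e-8)))
        if rel < tol and abs(d_ll) < 1e-6:
            converged = True
            break

    # SEs from the AI matrix over free components at the optimum
    tr, quad, t = stats(P, Py)
    free_idx = np.flatnonzero(theta > 0.0)
    cov = np.zeros((3, 3))
    if free_idx.size:
        AI = np.empty((free_idx.size, free_idx.size))
        Pt = [P @ t[k] for k in free_idx]
        for a_, ka in enumerate(free_idx):
            for b_ in range(a_, free_idx.size):
                AI[a_, b_] = AI[b_, a_] = 0.5 * float(t[ka] @ Pt[b_])
        try:
            Cfree = inv_psd(AI)
            cov[np.ix_(free_idx, free_idx)] = Cfree
        except np.linalg.LinAlgError:  # pragma: no cover - ill-conditioned edge
            cov[:] = np.nan
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))

    sp = float(theta.sum())
    if sp > 0:
        grad_h2 = np.array(
            [(sp - theta[0]) / sp**2, -theta[0] / sp**2, -theta[0] / sp**2]
        )
        se_h2 = float(np.sqrt(max(grad_h2 @ cov @ grad_h2, 0.0)))
    else:
        se_h2 = float("nan")

    return VarianceComponents(
        sigma2_a=float(theta[0]),
        sigma2_d=float(theta[1]),
        sigma2_e=float(theta[2]),
        se_sigma2_a=float(ses[0]),
        se_sigma2_d=float(ses[1]),
        se_sigma2_e=float(ses[2]),
        se_h2=se_h2,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        loglik_trace=tuple(trace),
    )


@dataclass(frozen=True)
class MMESolution:
    """Solution of Henderson's mixed-model equations."""

    beta_hat: np.ndarray
    a_hat: np.ndarray
    d_hat: np.ndarray
    solution_residual_norm: float


def solve_mme(
    dm: DesignMatrices,
    A: RelationshipMatrix,
    D: RelationshipMatrix,
    vc: VarianceComponents,
) -> MMESolution:
    """Fixed-effect estimates and additive/dominance BLUPs at given components.

    Builds Henderson's equations with variance ratios ``se2/sa2`` and
    ``se2/sd2`` added to the ``A``-inverse and ``D``-inverse blocks.  A
    random effect whose variance is zero is dropped from the equations and
    its BLUP vector returned as exact zeros.
    """
    if vc.sigma2_e <= 0:
        raise ValueError("solve_mme requires a positive residual variance")
    for M, name in ((A, "A"), (D, "D")):
        if tuple(M.ids) != tuple(dm.animal_ids):
            raise ValueError(f"{name} matrix ids do not match the design matrices")
    X, y = dm.X, dm.y
    Z = dm.Z
    q = dm.n_animals
    blocks: list[np.ndarray] = [X]
    use_a = vc.sigma2_a > 0
    use_d = vc.sigma2_d > 0
    if use_a:
        blocks.append(Z)
    if use_d:
        blocks.append(Z)  # W = Z: same record-to-animal incidence
    T = np.hstack(blocks)
    C = T.T @ T
    rhs = T.T @ y
    pos = X.shape[1]
    if use_a:
        C[pos : pos + q, pos : pos + q] += inv_psd(A.values) * (
            vc.sigma2_e / vc.sigma2_a
        )
        pos += q
    if use_d:
        C[pos : pos + q, pos : pos + q] += inv_psd(D.values) * (
            vc.sigma2_e / vc.sigma2_d
        )
    sol = np.linalg.solve(C, rhs)
    resid = float(np.max(np.abs(C @ sol - rhs))) / max(1.0, float(np.max(np.abs(rhs))))
    beta = sol[: X.shape[1]]
    pos = X.shape[1]
    a_hat = np.zeros(q)
    d_hat = np.zeros(q)
    if use_a:
        a_hat = sol[pos : pos + q]
        pos += q
    if use_d:
        d_hat = sol[pos : pos + q]
    return MMESolution(
        beta_hat=beta, a_hat=a_hat, d_hat=d_hat, solution_residual_norm=resid
    )


@dataclass(frozen=True)
class GeneticParameters:
    """Derived genetic parameters of one age: total variance and ratios."""

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    sigma2_p: float
    h2: float
    d_ratio: float

    def round(self, ndigits: int = 2) -> "GeneticParameters":
        """Report-layer rounding; the unrounded values stay authoritative."""
        r = lambda x: round(x, ndigits) if np.isfinite(x) else x
        return GeneticParameters(*(r(getattr(self, f)) for f in (
            "sigma2_a", "sigma2_d", "sigma2_e", "sigma2_p", "h2", "d_ratio")))


def genetic_parameters(
    sigma2_a: float | VarianceComponents,
    sigma2_d: float | None = None,
    sigma2_e: float | None = None,
) -> GeneticParameters:
    """Total phenotypic variance, heritability and dominance ratio.

    Accepts either the three components or a :class:`VarianceComponents`.
    With a zero total variance the ratios are undefined and reported as NaN.
    """
    if isinstance(sigma2_a, VarianceComponents):
        sa, sd, se = sigma2_a.sigma2_a, sigma2_a.sigma2_d, sigma2_a.sigma2_e
    else:
        sa, sd, se = float(sigma2_a), float(sigma2_d), float(sigma2_e)
    if min(sa, sd, se) < 0:
        raise ValueError("variance components must be non-negative")
    sp = sa + sd + se
    if sp > 0:
        return GeneticParameters(sa, sd, se, sp, sa / sp, sd / sp)
    return GeneticParameters(sa, sd, se, sp, float("nan"), float("nan"))


class AdditiveDominanceModel:
    """Animal model ``y = Xb + Za + Wd + e`` built from data tables.

    Parameters
    ----------
    dm : DesignMatrices
    A, D : RelationshipMatrix
        Additive and dominance covariance structures over the pedigree.

    Use :meth:`from_tables` to construct directly from a phenotype table
    and a :class:`~kradom.pedigree.Pedigree`; :meth:`fit` runs REML and
    returns an :class:`AdditiveDominanceResults`.
    """

    def __init__(self, dm: DesignMatrices, A: RelationshipMatrix, D: RelationshipMatrix):
        _v_parts(dm, A, D)  # validates id alignment
        self.dm = dm
        self.A = A
        self.D = D

    @classmethod
    def from_tables(
        cls,
        pheno: pd.DataFrame,
        ped: Pedigree,
        age: int | None = None,
        trait: str = "bw_g",
        fixed_effects: Sequence[str] = ("sex", "hatch"),
        lines: Sequence[str] | None = None,
    ) -> "AdditiveDominanceModel":
        """Build the model from a phenotype table and a pedigree.

        ``lines`` restricts the records to animals of the given pedigree
        line labels (e.g. ``("KR",)`` to fit on the cross only, as when the
        response is crossbred body weight); the full pedigree still drives
        the relationship structure and all animals receive BLUPs.
        """
        from .pedigree import additive_relationship_matrix, dominance_relationship_matrix

        if not ped.is_ordered:
            ped = topological_order(ped)
        if lines is not None:
            keep = {r.animal for r in ped if r.line in set(lines)}
            pheno = pheno[pheno["animal"].astype(str).isin(keep)]
        spec = ModelSpec(trait=trait, age=age, fixed_effects=tuple(fixed_effects))
        dm = build_design_matrices(pheno, ped, spec)
        A = additive_relationship_matrix(ped)
        D = dominance_relationship_matrix(ped, A)
        return cls(dm, A, D)

    def loglike(self, theta: Sequence[float]) -> float:
        """Restricted log-likelihood at ``(sa2, sd2, se2)``."""
        return restricted_loglik(theta, self.dm, self.A, self.D)

    def fit(
        self,
        init: Sequence[float] | None = None,
        tol: float = 1e-8,
        max_iter: int = 200,
    ) -> "AdditiveDominanceResults":
        vc = reml_estimate(self.dm, self.A, self.D, init=init, tol=tol, max_iter=max_iter)
        return AdditiveDominanceResults(self, vc)


class AdditiveDominanceResults:
    """REML fit of an :class:`AdditiveDominanceModel`.

    Carries the variance components with their AI standard errors, the
    derived genetic parameters, and (lazily) the mixed-model-equation
    solution with fixed-effect estimates and per-animal BLUPs.
    """

    def __init__(self, model: AdditiveDominanceModel, vc: VarianceComponents):
        self.model = model
        self.vc = vc

    # -- variance components -------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            [self.vc.sigma2_a, self.vc.sigma2_d, self.vc.sigma2_e],
            index=["sigma2_a", "sigma2_d", "sigma2_e"],
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            [self.vc.se_sigma2_a, self.vc.se_sigma2_d, self.vc.se_sigma2_e],
            index=["sigma2_a", "sigma2_d", "sigma2_e"],
        )

    @property
    def sigma2_p(self) -> float:
        return self.vc.sigma2_p

    @property
    def h2(self) -> float:
        return self.vc.h2

    @property
    def d_ratio(self) -> float:
        return self.vc.d_ratio

    @property
    def se_h2(self) -> float:
        return self.vc.se_h2

    @property
    def loglik(self) -> float:
        return self.vc.loglik

    @property
    def converged(self) -> bool:
        return self.vc.converged

    @property
    def genetic_params(self) -> GeneticParameters:
        return genetic_parameters(self.vc)

    # -- BLUPs ----------------------------------------------------------------

    @cached_property
    def mme(self) -> MMESolution:
        """Mixed-model-equation solution at the estimated components.

        When the residual variance is pinned at the zero boundary (as can
        happen when genetic variance dominates) the equations are solved
        with a vanishing residual ridge, ``1e-8 * sigma2_p``, so BLUPs
        remain defined in the near-interpolation limit.
        """
        vc = self.vc
        if vc.sigma2_e == 0.0:
            if vc.sigma2_p <= 0.0:
                raise ValueError("all variance components are zero; no BLUPs")
            from dataclasses import replace

            vc = replace(vc, sigma2_e=1e-8 * vc.sigma2_p)
        return solve_mme(self.model.dm, self.model.A, self.model.D, vc)

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.mme.beta_hat, index=list(self.model.dm.x_names))

    @property
    def a_hat(self) -> pd.Series:
        return pd.Series(self.mme.a_hat, index=list(self.model.dm.animal_ids))

    @property
    def d_hat(self) -> pd.Series:
        return pd.Series(self.mme.d_hat, index=list(self.model.dm.animal_ids))

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        vc = self.vc
        lines = [
            "Additive + dominance animal model (REML)",
            "=" * 48,
            f"records: {self.model.dm.n_records}   animals: {self.model.dm.n_animals}",
            f"converged: {vc.converged}   iterations: {vc.n_iter}",
            f"restricted log-likelihood: {vc.loglik:.4f}",
            "",
            f"{'component':<12}{'estimate':>14}{'std. error':>14}",
            "-" * 40,
            f"{'sigma2_a':<12}{vc.sigma2_a:>14.4f}{vc.se_sigma2_a:>14.4f}",
            f"{'sigma2_d':<12}{vc.sigma2_d:>14.4f}{vc.se_sigma2_d:>14.4f}",
            f"{'sigma2_e':<12}{vc.sigma2_e:>14.4f}{vc.se_sigma2_e:>14.4f}",
            f"{'sigma2_p':<12}{vc.sigma2_p:>14.4f}",
            "",
            f"h2 = {vc.h2:.4f} (SE {vc.se_h2:.4f})   sd2/sp2 = {vc.d_ratio:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<AdditiveDominanceResults h2={self.h2:.3f} "
            f"d_ratio={self.d_ratio:.3f} converged={self.converged}>"
        )


def fit_report(fits: Mapping[int, VarianceComponents], ndigits: int = 2) -> pd.DataFrame:
    """Genetic-parameter report by age: one column per age, rows mirroring
    the standard crossbreeding report (components, total, h2, SE, ratio)."""
    rows = ["sigma2_a", "sigma2_d", "sigma2_e", "sigma2_p", "h2", "se_h2", "d_ratio"]
    out = {}
    for age in sorted(fits):
        vc = fits[age]
        out[age] = [
            round(vc.sigma2_a, ndigits),
            round(vc.sigma2_d, ndigits),
            round(vc.sigma2_e, ndigits),
            round(vc.sigma2_p, ndigits),
            round(vc.h2, ndigits) if np.isfinite(vc.h2) else np.nan,
            round(vc.se_h2, ndigits) if np.isfinite(vc.se_h2) else np.nan,
            round(vc.d_ratio, ndigits) if np.isfinite(vc.d_ratio) else np.nan,
        ]
    return pd.DataFrame(out, index=rows)
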