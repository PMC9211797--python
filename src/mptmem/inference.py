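"""Maximum-likelihood estimation and inference for MPT models.

Fitting maximizes the product-multinomial log-likelihood

.. math::

    \\ell(\\theta) = \\sum_{j} \\sum_{c} n_{jc} \\log p_{jc}(\\theta),

where :math:`n_{jc}` is the observed count and :math:`p_{jc}(\\theta)`
the model category probability in tree :math:`j`, category :math:`c`.
Goodness of fit is the likelihood-ratio statistic
:math:`G^2 = 2 \\sum n_{jc} \\log(n_{jc}/\\hat n_{jc})` with
:math:`0 \\log 0 := 0`, referred to a central chi-square with
``df = sum_trees(categories - 1) - #free parameters``.

Two interchangeable optimizers are provided: the classical MPT
expectation-maximization update on latent branch frequencies, and
quasi-Newton (L-BFGS-B) maximization after a logit transform of each
free parameter.  Agreement between the two backends is the package's
internal cross-check of optimizer fidelity.

Nested models are compared with :math:`\\Delta G^2` likelihood-ratio
tests; effect sizes use Cohen's :math:`w = \\sqrt{\\Delta G^2 / N}` and
power calculations the noncentral chi-square distribution with
noncentrality :math:`\\lambda = N w^2`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .core import (
    ExpansionMap,
    FrequencyTable,
    MPTModel,
    Restriction,
    RestrictionError,
    apply_restrictions,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "LRTestResult",
    "PowerQuery",
    "fit_mle",
    "standard_errors",
    "lr_test",
    "effect_size_w",
    "chi2_power",
    "minimal_detectable_w",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20220621

# parameters are kept strictly inside the unit interval during optimization;
# an estimate this close to 0 or 1 is reported as a boundary estimate
_CLAMP = 1e-8
_BOUNDARY_TOL = 1e-6


# --------------------------------------------------------------------------
# Compiled likelihood kernel
# --------------------------------------------------------------------------

class _Kernel:
    """Vectorized likelihood machinery for one (model, data) pair.

    Branch probabilities are ``const_b * prod_k theta_k^A[b,k] *
    (1-theta_k)^B[b,k]`` where ``A``/``B`` count direct/complement
    occurrences of each *free* parameter and ``const_b`` collects the
    contribution of fixed parameters.
    """

    def __init__(self, model: MPTModel, data: "FrequencyTable | Mapping"):
        if isinstance(data, FrequencyTable):
            data.validate_against(model)
            lookup = data.counts
        else:
            lookup = dict(data)  # real-valued pseudo-counts are allowed
        self.model = model
        self.free = list(model.free_params)
        k = len(self.free)
        idx = {p: j for j, p in enumerate(self.free)}

        cells = [(t.name, c) for t in model.trees for c in t.categories]
        cell_idx = {cell: i for i, cell in enumerate(cells)}
        self.cells = cells
        self.n = np.array([lookup.get(cell, 0) for cell in cells], dtype=float)
        self.tree_of_cell = np.array(
            [ti for ti, t in enumerate(model.trees) for _ in t.categories]
        )
        self.totals = np.bincount(
            self.tree_of_cell, weights=self.n, minlength=len(model.trees)
        )

        nb = len(model.branches)
        self.A = np.zeros((nb, k))
        self.B = np.zeros((nb, k))
        self.const = np.ones(nb)
        self.cell_of_branch = np.empty(nb, dtype=int)
        for bi, b in enumerate(model.branches):
            self.cell_of_branch[bi] = cell_idx[(b.tree, b.category)]
            for term in b.terms:
                if term.param in model.fixed:
                    v = model.fixed[term.param]
                    self.const[bi] *= (1.0 - v) if term.complement else v
                elif term.complement:
                    self.B[bi, idx[term.param]] += 1.0
                else:
                    self.A[bi, idx[term.param]] += 1.0

        # saturated log-likelihood: observed proportions as probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            phat = self.n / self.totals[self.tree_of_cell]
            terms = np.where(self.n > 0, self.n * np.log(phat), 0.0)
        self.loglik_saturated = float(terms.sum())

    # -- probabilities ----------------------------------------------------

    def branch_probs(self, theta: np.ndarray) -> np.ndarray:
        logp = self.A @ np.log(theta) + self.B @ np.log1p(-theta)
        return self.const * np.exp(logp)

    def cell_probs(self, theta: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.cell_of_branch,
            weights=self.branch_probs(theta),
            minlength=len(self.cells),
        )

    def loglik(self, theta: np.ndarray) -> float:
        p = self.cell_probs(theta)
        mask = self.n > 0
        if np.any(p[mask] <= 0):
            return -np.inf
        return float(self.n[mask] @ np.log(p[mask]))

    def grad_loglik(self, theta: np.ndarray) -> np.ndarray:
        pb = self.branch_probs(theta)
        p = np.bincount(self.cell_of_branch, weights=pb, minlength=len(self.cells))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p > 0, self.n / p, 0.0)
        w = ratio[self.cell_of_branch] * pb
        return (w @ self.A) / theta - (w @ self.B) / (1.0 - theta)

    def g2(self, theta: np.ndarray) -> float:
        """Likelihood-ratio fit statistic at theta (inf if an expected
        cell is empty while observed is not)."""
        ll = self.loglik(theta)
        if not np.isfinite(ll):
            return np.inf
        return max(2.0 * (self.loglik_saturated - ll), 0.0)

    # -- optimizers -------------------------------------------------------

    def em_step(self, theta: np.ndarray) -> np.ndarray:
        pb = self.branch_probs(theta)
        p = np.bincount(self.cell_of_branch, weights=pb, minlength=len(self.cells))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p > 0, self.n / p, 0.0)
        m = ratio[self.cell_of_branch] * pb  # expected branch counts
        num = m @ self.A
        den = m @ (self.A + self.B)
        new = np.where(den > 0, num / np.maximum(den, 1e-300), theta)
        return np.clip(new, _CLAMP, 1.0 - _CLAMP)

    def fit_em(self, start: np.ndarray, tol: float, max_iter: int):
        theta = np.clip(start, _CLAMP, 1.0 - _CLAMP)
        ll = self.loglik(theta)
        for it in range(1, max_iter + 1):
            theta = self.em_step(theta)
            new_ll = self.loglik(theta)
            if new_ll - ll < tol:
                return theta, new_ll, it, True
            ll = new_ll
        return theta, ll, max_iter, False

    def fit_logit(self, start: np.ndarray, tol: float, max_iter: int):
        x0 = special.logit(np.clip(start, _CLAMP, 1.0 - _CLAMP))

        def neg(x: np.ndarray):
            theta = special.expit(x)
            theta = np.clip(theta, _CLAMP, 1.0 - _CLAMP)
            ll = self.loglik(theta)
            if not np.isfinite(ll):
                return 1e300, np.zeros_like(x)
            g = self.grad_loglik(theta) * theta * (1.0 - theta)
            return -ll, -g

        res = optimize.minimize(
            neg, x0, jac=True, method="L-BFGS-B",
            bounds=[(-18.5, 18.5)] * len(x0),
            options={"maxiter": max_iter, "ftol": 1e-16, "gtol": 1e-12,
                     "maxcor": 30},
        )
        theta = np.clip(special.expit(res.x), _CLAMP, 1.0 - _CLAMP)
        ll = self.loglik(theta)
        # L-BFGS-B line searches can fail harmlessly at machine precision;
        # a vanishing EM improvement certifies stationarity either way
        gain = np.inf
        for _ in range(5):
            if gain < 1e-9:
                break
            polished = self.em_step(theta)
            new_ll = self.loglik(polished)
            gain = new_ll - ll
            if new_ll > ll:
                theta, ll = polished, new_ll
        return theta, ll, int(res.nit), bool(res.success) or gain < 1e-7


# --------------------------------------------------------------------------
# Results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Controls for the maximum-likelihood fit.

    ``n_starts`` random starting points are used in addition to the
    midpoint start (all parameters at 0.5); the best log-likelihood wins.
    """

    backend: str = "logit"  # "logit" | "em"
    n_starts: int = 10
    seed: int = DEFAULT_SEED
    tol: float = 1e-10
    max_iter: int = 10_000
    compute_se: bool = True


@dataclass(frozen=True)
class FitResult:
    """A maximum-likelihood fit of an (optionally restricted) MPT model."""

    estimates: dict[str, float]          # reduced (free) parameter space
    expanded: dict[str, float]           # full parameter space
    se: dict[str, float | None]          # None marks boundary/singular SEs
    loglik: float
    G2: float
    df: int
    p: float
    converged: bool
    n_iter: int
    n_starts: int
    seed: int
    backend: str
    n_total: int
    reduced_model: MPTModel = field(repr=False, compare=False)
    expansion: ExpansionMap = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "expanded": self.expanded,
            "se": self.se,
            "loglik": self.loglik,
            "G2": self.G2,
            "df": self.df,
            "p": self.p,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "backend": self.backend,
            "n_total": self.n_total,
        }


@dataclass(frozen=True)
class LRTestResult:
    """A nested likelihood-ratio test between two restriction sets."""

    delta_G2: float
    df: int
    p: float
    w: float
    base_fit: FitResult = field(repr=False, compare=False)
    restricted_fit: FitResult = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "delta_G2": self.delta_G2,
            "df": self.df,
            "p": self.p,
            "w": self.w,
            "base_G2": self.base_fit.G2,
            "restricted_G2": self.restricted_fit.G2,
        }


@dataclass(frozen=True)
class PowerQuery:
    """A chi-square power/sensitivity computation and its result."""

    N: int
    df: int
    alpha: float
    w: float
    power: float

    @property
    def noncentrality(self) -> float:
        return self.N * self.w**2

    def to_dict(self) -> dict:
        return {
            "N": self.N, "df": self.df, "alpha": self.alpha,
            "w": self.w, "power": self.power, "lambda": self.noncentrality,
        }


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _multi_start(kern: _Kernel, opts: FitOptions):
    """Run the selected optimizer from the midpoint plus random starts and
    keep the best log-likelihood."""
    if opts.backend not in ("em", "logit"):
        raise ValueError(f"unknown backend {opts.backend!r}")
    k = len(kern.free)
    rng = np.random.default_rng(opts.seed)
    starts = [np.full(k, 0.5)]
    starts += [rng.uniform(0.05, 0.95, size=k) for _ in range(opts.n_starts)]
    runner = kern.fit_em if opts.backend == "em" else kern.fit_logit

    best = None
    any_converged = False
    for s in starts:
        theta, ll, n_iter, ok = runner(s, opts.tol, opts.max_iter)
        any_converged = any_converged or ok
        if best is None or ll > best[1]:
            best = (theta, ll, n_iter, ok)
    if not any_converged:
        warnings.warn("no start converged; reporting best point found")
    theta, ll, n_iter, ok = best
    return theta, ll, n_iter, ok, len(starts)


def fit_mle(
    model: MPTModel,
    data: FrequencyTable,
    restrictions: Sequence[Restriction] = (),
    options: FitOptions | None = None,
) -> FitResult:
    """Fit an MPT model to a frequency table by maximum likelihood.

    Restrictions are applied first; the reduced model's free parameters
    are estimated from multiple starting points and the best solution
    kept.  Non-convergence of every start is flagged on the result, never
    silent.
    """
    opts = options or FitOptions()
    reduced, expansion = apply_restrictions(model, restrictions)
    kern = _Kernel(reduced, data)
    k = len(kern.free)
    theta, ll, n_iter, ok, n_starts = _multi_start(kern, opts)

    estimates = dict(zip(kern.free, theta.tolist()))
    expanded = expansion.expand(estimates) if k else dict(expansion.constants)

    se: dict[str, float | None]
    if opts.compute_se and k:
        se = standard_errors(model, data, estimates, restrictions=restrictions)
    else:
        se = {p: None for p in kern.free}

    g2 = kern.g2(theta)
    df = reduced.data_df - k
    p = 1.0 if df <= 0 else float(stats.chi2.sf(g2, df))
    return FitResult(
        estimates=estimates,
        expanded=expanded,
        se=se,
        loglik=ll,
        G2=g2,
        df=df,
        p=p,
        converged=ok,
        n_iter=n_iter,
        n_starts=n_starts,
        seed=opts.seed,
        backend=opts.backend,
        n_total=data.total,
        reduced_model=reduced,
        expansion=expansion,
    )


def standard_errors(
    model: MPTModel,
    data: FrequencyTable,
    estimates: Mapping[str, float],
    restrictions: Sequence[Restriction] = (),
    step: float = 1e-5,
) -> dict[str, float | None]:
    """Asymptotic standard errors from the observed Fisher information.

    The information matrix is the negative Hessian of the log-likelihood
    in the reduced parameter space, evaluated at the supplied estimates by
    central differences of the analytic gradient.  Parameters at the
    boundary of the unit interval, or with singular information, receive
    ``None`` and a warning: the asymptotic theory does not apply there.
    """
    reduced, _ = apply_restrictions(model, restrictions)
    kern = _Kernel(reduced, data)
    theta = np.array([estimates[p] for p in kern.free])
    k = len(theta)

    boundary = (theta < _BOUNDARY_TOL) | (theta > 1.0 - _BOUNDARY_TOL)
    interior = ~boundary
    se: dict[str, float | None] = {p: None for p in kern.free}
    if boundary.any():
        warnings.warn(
            "boundary estimates for "
            + ", ".join(np.array(kern.free)[boundary]) + "; SEs unavailable"
        )
    if not interior.any():
        return se

    hess = np.empty((k, k))
    for j in range(k):
        up, dn = theta.copy(), theta.copy()
        h = step * max(1.0, abs(theta[j]))
        up[j] = min(up[j] + h, 1.0 - _CLAMP)
        dn[j] = max(dn[j] - h, _CLAMP)
        hess[:, j] = (kern.grad_loglik(up) - kern.grad_loglik(dn)) / (up[j] - dn[j])
    hess = 0.5 * (hess + hess.T)
    info = -hess[np.ix_(interior, interior)]
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; SEs unavailable")
        return se
    diag = np.diag(cov)
    if np.any(diag <= 0):
        warnings.warn("non-positive-definite observed information")
    names = np.array(kern.free)[interior]
    for name, v in zip(names, diag):
        se[name] = float(np.sqrt(v)) if v > 0 else None
    return se


# --------------------------------------------------------------------------
# Likelihood-ratio tests
# --------------------------------------------------------------------------

def lr_test(
    model: MPTModel,
    data: FrequencyTable,
    base: Sequence[Restriction] = (),
    extra: Sequence[Restriction] = (),
    N: int | None = None,
    options: FitOptions | None = None,
) -> LRTestResult:
    """Likelihood-ratio test of ``extra`` restrictions on top of ``base``.

    The restricted model (``base`` plus ``extra``) is nested in the base
    model by construction; its excess misfit ``delta_G2 = G2_restricted -
    G2_base`` is referred to a central chi-square whose df is the number
    of free parameters removed by ``extra``.  ``N`` (defaulting to the
    table's total count) converts the statistic to Cohen's
    ``w = sqrt(delta_G2 / N)``.
    """
    base_fit = fit_mle(model, data, base, options)
    restricted_fit = fit_mle(model, data, list(base) + list(extra), options)
    df = len(base_fit.estimates) - len(restricted_fit.estimates)
    if df < 1:
        raise RestrictionError(
            "extra restrictions do not remove any free parameter; "
            "the models are not strictly nested"
        )
    delta = restricted_fit.G2 - base_fit.G2
    if delta < -1e-6:
        warnings.warn(
            f"restricted model fit better than base (delta_G2 = {delta:.3g}); "
            "check optimizer convergence"
        )
    delta = max(delta, 0.0)
    n_total = data.total if N is None else N
    return LRTestResult(
        delta_G2=delta,
        df=df,
        p=float(stats.chi2.sf(delta, df)),
        w=effect_size_w(delta, n_total),
        base_fit=base_fit,
        restricted_fit=restricted_fit,
    )


# --------------------------------------------------------------------------
# Effect size and power
# --------------------------------------------------------------------------

def effect_size_w(G2: float, N: int) -> float:
    """Cohen's effect size ``w = sqrt(G2 / N)`` for chi-square statistics."""
    if N <= 0:
        raise ValueError("N must be positive")
    if G2 < 0:
        raise ValueError("G2 must be nonnegative")
    return float(np.sqrt(G2 / N))


def chi2_power(w: float, N: int, df: int, alpha: float) -> float:
    """Power of a chi-square test at effect size ``w``.

    The test statistic is distributed as noncentral chi-square with
    noncentrality ``lambda = N * w**2`` under the alternative; power is
    the probability of exceeding the central critical value at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    lam = N * w**2
    crit = stats.chi2.ppf(1.0 - alpha, df)
    if lam == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, lam))


def minimal_detectable_w(
    N: int, df: int, alpha: float, power: float
) -> PowerQuery:
    """Sensitivity analysis: smallest effect size w detectable at given
    power.

    Root-finds the noncentrality ``lambda*`` at which the noncentral
    chi-square test attains the target power, then converts through
    ``w = sqrt(lambda* / N)``.
    """
    if not 0 < alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    crit = stats.chi2.ppf(1.0 - alpha, df)

    def gap(lam: float) -> float:
        return stats.ncx2.sf(crit, df, lam) - power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("power target not bracketable")
    lam_star = optimize.brentq(gap, 1e-12, hi, xtol=1e-12, rtol=1e-14)
    w = float(np.sqrt(lam_star / N))
    return PowerQuery(N=N, df=df, alpha=alpha, w=w,
                      power=chi2_power(w, N, df, alpha))
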