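"""Synthetic data, parameter recovery, and empirical power studies.

The generator draws each tree's category counts from a multinomial
distribution at the model's category probabilities, i.e. it emulates the
pooled (complete-pooling) sampling scheme that the aggregate analysis
assumes: every response is an independent draw, with no participant-level
heterogeneity.  Recovery and power studies re-fit each simulated table
and summarize estimator bias, RMSE, confidence-interval coverage, and
likelihood-ratio rejection rates against their analytic counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    FrequencyTable,
    MPTModel,
    Restriction,
    apply_restrictions,
    category_probabilities,
)
from .inference import FitOptions, effect_size_w, fit_mle, lr_test

__all__ = [
    "SimulationSpec",
    "RecoverySummary",
    "sample_frequencies",
    "recovery_study",
    "empirical_power",
    "expected_table",
    "population_w",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate frequency tables from an MPT model."""

    model: MPTModel
    true_params: Mapping[str, float]
    per_tree_totals: Mapping[str, int]
    reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for tree, n in self.per_tree_totals.items():
            if n <= 0:
                raise ValueError(f"total for tree {tree!r} must be positive")


def sample_frequencies(spec: SimulationSpec, rep_index: int = 0) -> FrequencyTable:
    """Draw one replicate table: independent multinomials per tree.

    Reproducible given ``(spec.seed, rep_index)``; each replicate uses an
    independent random stream.
    """
    rng = np.random.default_rng([spec.seed, rep_index])
    probs = category_probabilities(spec.model, spec.true_params)
    counts: dict[tuple[str, str], int] = {}
    for tree in spec.model.trees:
        p = np.array([probs[tree.name][c] for c in tree.categories])
        draw = rng.multinomial(spec.per_tree_totals[tree.name], p / p.sum())
        for cat, n in zip(tree.categories, draw):
            counts[(tree.name, cat)] = int(n)
    return FrequencyTable(counts)


def expected_table(spec: SimulationSpec) -> FrequencyTable:
    """Expected counts at the true parameters, largest-remainder rounded
    to integers (used for 'infinite-N'-style noncentrality targets)."""
    from .models import reconstruct_counts

    probs = category_probabilities(spec.model, spec.true_params)
    counts: dict[tuple[str, str], int] = {}
    for tree in spec.model.trees:
        p = [probs[tree.name][c] for c in tree.categories]
        row = reconstruct_counts(p, spec.per_tree_totals[tree.name])
        for cat, n in zip(tree.categories, row):
            counts[(tree.name, cat)] = n
    return FrequencyTable(counts)


@dataclass(frozen=True)
class RecoverySummary:
    """Per-parameter recovery diagnostics over simulation replicates."""

    truth: dict[str, float]            # reduced-space true values
    mean_estimate: dict[str, float]
    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float | None]  # SE-based 95% intervals; None if no SE
    reps: int
    n_converged: int
    n_excluded: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "truth": self.truth,
            "mean_estimate": self.mean_estimate,
            "bias": self.bias,
            "rmse": self.rmse,
            "coverage": self.coverage,
            "reps": self.reps,
            "n_converged": self.n_converged,
            "n_excluded": self.n_excluded,
            "seed": self.seed,
        }


def recovery_study(
    spec: SimulationSpec,
    restrictions: Sequence[Restriction] = (),
    options: FitOptions | None = None,
) -> RecoverySummary:
    """Fit every simulated replicate and summarize estimator behaviour.

    The truth is projected into the reduced space of the restricted model
    (the restriction's representative parameter carries the value), so
    bias/RMSE/coverage are reported for exactly the free parameters that
    were estimated.  Replicates whose fit does not converge are excluded
    from the summaries and counted.
    """
    reduced, expansion = apply_restrictions(spec.model, restrictions)
    free = list(reduced.free_params)
    truth = {p: float(spec.true_params[p]) for p in free}
    opts = options or FitOptions()

    est = {p: [] for p in free}
    covered = {p: [] for p in free}
    n_converged = 0
    n_excluded = 0
    for rep in range(spec.reps):
        table = sample_frequencies(spec, rep)
        fit = fit_mle(spec.model, table, restrictions, opts)
        if not fit.converged:
            n_excluded += 1
            continue
        n_converged += 1
        for p in free:
            e = fit.estimates[p]
            est[p].append(e)
            se = fit.se.get(p)
            if se is not None:
                covered[p].append(abs(e - truth[p]) <= 1.959964 * se)

    mean_est, bias, rmse, coverage = {}, {}, {}, {}
    for p in free:
        arr = np.array(est[p])
        if arr.size == 0:
            mean_est[p] = bias[p] = rmse[p] = float("nan")
            coverage[p] = None
            continue
        mean_est[p] = float(arr.mean())
        bias[p] = float(arr.mean() - truth[p])
        rmse[p] = float(np.sqrt(np.mean((arr - truth[p]) ** 2)))
        cov = covered[p]
        coverage[p] = float(np.mean(cov)) if cov else None
    return RecoverySummary(
        truth=truth, mean_estimate=mean_est, bias=bias, rmse=rmse,
        coverage=coverage, reps=spec.reps, n_converged=n_converged,
        n_excluded=n_excluded, seed=spec.seed,
    )


def empirical_power(
    spec: SimulationSpec,
    base: Sequence[Restriction],
    extra: Sequence[Restriction],
    alpha: float = 0.05,
    options: FitOptions | None = None,
) -> float:
    """Monte-Carlo rejection rate of the likelihood-ratio test of
    ``extra`` on top of ``base`` across the replicates of ``spec``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    opts = options or FitOptions()
    rejections = 0
    n_used = 0
    for rep in range(spec.reps):
        table = sample_frequencies(spec, rep)
        res = lr_test(spec.model, table, base, extra, options=opts)
        if not (res.base_fit.converged and res.restricted_fit.converged):
            continue
        n_used += 1
        rejections += res.p < alpha
    if n_used == 0:
        raise RuntimeError("no replicate produced a converged test")
    return rejections / n_used


def population_w(
    model: MPTModel,
    true_params: Mapping[str, float],
    per_tree_totals: Mapping[str, int],
    restrictions: Sequence[Restriction],
    options: FitOptions | None = None,
) -> float:
    """Population effect size of a restriction set at given true
    parameters.

    Fits the restricted model to the exact expected cell probabilities
    (weighted by the per-tree totals) and converts the resulting misfit
    per observation into Cohen's w — the standard noncentrality
    construction for chi-square power analysis.  Zero when the truth
    satisfies the restrictions.
    """
    from .inference import _Kernel, _multi_start

    probs = category_probabilities(model, true_params)
    reduced, _ = apply_restrictions(model, restrictions)
    N = sum(per_tree_totals[t.name] for t in model.trees)
    expected = {
        (t.name, c): per_tree_totals[t.name] * probs[t.name][c]
        for t in model.trees for c in t.categories
    }
    kern = _Kernel(reduced, expected)
    opts = options or FitOptions()
    theta, _, _, _, _ = _multi_start(kern, opts)
    return effect_size_w(kern.g2(theta), N)
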