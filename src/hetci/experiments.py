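"""Monte-Carlo evaluation of the tau^2 interval methods.

Coverage/width experiments over simulation conditions, zero-cell
subset analyses, the distribution study of the generalized Q
statistic, condition grids for coverage maps, and the bias-coverage
correlation.  Repetitions use independent seed-sequence substreams so
results are reproducible and invariant to the worker count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .simulate import SimCondition, simulate_meta
from .tau2 import (
    Interval,
    IntervalStatus,
    MetaSample,
    WeightScheme,
    generalized_q,
    genq_ci,
    paule_mandel,
    q_profile_ci,
    weighted_mean,
)

__all__ = [
    "METHODS",
    "CoverageResult",
    "QDistSummary",
    "evaluate_coverage",
    "subset_coverage",
    "qstat_distribution",
    "coverage_grid",
    "bias_coverage_correlation",
    "build_preset",
    "PRESETS",
]

#: Interval methods under study, keyed by the names used in all outputs.
METHODS: Mapping[str, Callable[[MetaSample, float], Interval]] = {
    "qprofile": lambda s, level: q_profile_ci(s, level),
    "genq_variance": lambda s, level: genq_ci(s, WeightScheme.INVERSE_VARIANCE, level),
    "genq_se": lambda s, level: genq_ci(s, WeightScheme.INVERSE_SE, level),
}

ACCEPTABLE_COVERAGE = 0.9  # threshold used for grid acceptability flags


@dataclass(frozen=True)
class CoverageResult:
    """Per-repetition interval outcomes for one simulation condition."""

    condition: SimCondition
    methods: tuple[str, ...]
    level: float
    covered: dict  # method -> bool array (reps,)
    width: dict  # method -> float array, nan where null set
    null_set: dict  # method -> bool array
    any_zero: np.ndarray  # rep had >= 1 study with a zero cell
    any_two_zero: np.ndarray  # rep had >= 1 study with two zero cells
    mu_hat: np.ndarray  # random-effects mean estimate (PM weights) per rep

    def coverage(self, method: str) -> float:
        return float(np.mean(self.covered[method]))

    def mean_width(self, method: str) -> float:
        """Average width over non-null-set repetitions (nan if all null)."""
        w = self.width[method]
        finite = w[~np.isnan(w)]
        return float(finite.mean()) if finite.size else float("nan")

    def sd_width(self, method: str) -> float:
        w = self.width[method]
        finite = w[~np.isnan(w)]
        return float(finite.std(ddof=1)) if finite.size > 1 else float("nan")

    def null_set_proportion(self, method: str) -> float:
        return float(np.mean(self.null_set[method]))

    def width_wins(self, method_a: str, method_b: str) -> tuple[int, int, int]:
        """(a smaller, b smaller, ties) over reps where both widths exist."""
        wa, wb = self.width[method_a], self.width[method_b]
        both = ~np.isnan(wa) & ~np.isnan(wb)
        wins = int(np.sum(wa[both] < wb[both]))
        losses = int(np.sum(wb[both] < wa[both]))
        ties = int(both.sum()) - wins - losses
        return wins, losses, ties

    @property
    def mu_bias(self) -> float:
        """Mean over reps of mu_hat minus the true mu."""
        return float(np.mean(self.mu_hat)) - self.condition.mu

    def summary(self) -> pd.DataFrame:
        """One tidy row per method."""
        c = self.condition
        rows = []
        for m in self.methods:
            rows.append(
                {
                    "method": m,
                    "mu": c.mu,
                    "tau": c.tau,
                    "pi_c": c.pi_c,
                    "k": c.k,
                    "size_min": min(c.group_sizes),
                    "size_max": max(c.group_sizes),
                    "variance_mode": c.variance_mode,
                    "generator_mode": c.generator_mode,
                    "reps": c.reps,
                    "coverage": self.coverage(m),
                    "mean_width": self.mean_width(m),
                    "sd_width": self.sd_width(m),
                    "null_set_prop": self.null_set_proportion(m),
                    "zero_prop": float(np.mean(self.any_zero)),
                    "two_zero_prop": float(np.mean(self.any_two_zero)),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class QDistSummary:
    """Replicate generalized Q values and their reference-law moments."""

    condition: SimCondition
    q_values: np.ndarray
    tau2_eval: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.q_values))

    @property
    def variance(self) -> float:
        return float(np.var(self.q_values, ddof=1))

    @property
    def ref_mean(self) -> float:
        return float(self.condition.k - 1)

    @property
    def ref_variance(self) -> float:
        return float(2 * (self.condition.k - 1))

    @property
    def mean_ratio(self) -> float:
        """Empirical mean divided by the chi-squared mean k - 1."""
        return self.mean / self.ref_mean


def _child_rngs(condition: SimCondition) -> list[np.random.Generator]:
    """One independent substream per repetition (worker-count invariant)."""
    root = np.random.SeedSequence(condition.seed)
    return [np.random.default_rng(child) for child in root.spawn(condition.reps)]


def _one_coverage_rep(
    condition: SimCondition,
    rng: np.random.Generator,
    methods: Sequence[str],
    level: float,
):
    meta = simulate_meta(condition, rng)
    tau2_true = condition.tau2
    out = {}
    for m in methods:
        try:
            interval = METHODS[m](meta.sample, level)
        except Exception as exc:  # pragma: no cover - propagated with context
            raise RuntimeError(
                f"interval computation failed for method {m!r} under {condition}"
            ) from exc
        out[m] = (
            interval.contains(tau2_true),
            interval.width if interval.status is not IntervalStatus.NULL_SET else np.nan,
            interval.status is IntervalStatus.NULL_SET,
        )
    pm, _ = paule_mandel(meta.sample)
    mu_hat = weighted_mean(meta.sample.y, 1.0 / (pm + meta.sample.var))
    any_zero = bool(np.any(meta.zero_cells >= 1))
    any_two = bool(np.any(meta.zero_cells >= 2))
    return out, any_zero, any_two, mu_hat


def evaluate_coverage(
    condition: SimCondition,
    methods: Sequence[str] = tuple(METHODS),
    level: float = 0.95,
    n_jobs: int = 1,
) -> CoverageResult:
    """Coverage, width and null-set accounting for one condition.

    A repetition covers iff its interval is not the null set and
    ``lb <= tau^2 <= ub``; null-set repetitions are excluded from the
    width mean/SD and reported through the null-set proportion.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise KeyError(f"unknown methods: {sorted(unknown)}")
    rngs = _child_rngs(condition)
    if n_jobs == 1:
        results = [_one_coverage_rep(condition, r, methods, level) for r in rngs]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_coverage_rep)(condition, r, methods, level) for r in rngs
        )
    reps = condition.reps
    covered = {m: np.empty(reps, dtype=bool) for m in methods}
    width = {m: np.empty(reps) for m in methods}
    null_set = {m: np.empty(reps, dtype=bool) for m in methods}
    any_zero = np.empty(reps, dtype=bool)
    any_two = np.empty(reps, dtype=bool)
    mu_hat = np.empty(reps)
    for i, (per_method, z1, z2, mh) in enumerate(results):
        for m in methods:
            covered[m][i], width[m][i], null_set[m][i] = per_method[m]
        any_zero[i], any_two[i], mu_hat[i] = z1, z2, mh
    return CoverageResult(
        condition=condition,
        methods=tuple(methods),
        level=level,
        covered=covered,
        width=width,
        null_set=null_set,
        any_zero=any_zero,
        any_two_zero=any_two,
        mu_hat=mu_hat,
    )


def subset_coverage(result: CoverageResult) -> pd.DataFrame:
    """Coverage recomputed within zero-cell subsets of the repetitions.

    Rows per method x subset in {zero, nonzero, two_zero, not_two_zero},
    with the subset proportion; coverage is NaN for empty subsets.
    """
    masks = {
        "zero": result.any_zero,
        "nonzero": ~result.any_zero,
        "two_zero": result.any_two_zero,
        "not_two_zero": ~result.any_two_zero,
    }
    rows = []
    for m in result.methods:
        for name, mask in masks.items():
            n = int(mask.sum())
            cov = float(result.covered[m][mask].mean()) if n else float("nan")
            rows.append(
                {
                    "method": m,
                    "subset": name,
                    "proportion": n / mask.size,
                    "coverage": cov,
                    "n_reps": n,
                }
            )
    return pd.DataFrame(rows)


def _one_q_rep(condition: SimCondition, rng: np.random.Generator, tau2: float) -> float:
    meta = simulate_meta(condition, rng)
    return generalized_q(meta.sample, tau2)


def qstat_distribution(
    condition: SimCondition, reps: Optional[int] = None, n_jobs: int = 1
) -> QDistSummary:
    """Distribution of the generalized Q statistic at the true tau^2.

    Q is evaluated at the condition's true tau^2 with weights
    ``1/(tau^2 + v_i)`` (at tau = 0 this is Cochran's Q), with the
    variances v_i chosen by the condition's variance mode.  Under the
    model assumptions the values follow chi-squared with k - 1 df.
    """
    if reps is not None:
        condition = condition.with_(reps=reps)
    tau2 = condition.tau2
    rngs = _child_rngs(condition)
    if n_jobs == 1:
        q_values = np.array([_one_q_rep(condition, r, tau2) for r in rngs])
    else:
        q_values = np.array(
            Parallel(n_jobs=n_jobs)(
                delayed(_one_q_rep)(condition, r, tau2) for r in rngs
            )
        )
    return QDistSummary(condition=condition, q_values=q_values, tau2_eval=tau2)


def coverage_grid(
    conditions: Sequence[SimCondition],
    methods: Sequence[str] = tuple(METHODS),
    level: float = 0.95,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Long-format coverage table over a grid of conditions.

    One row per (method, condition) with coverage and an acceptability
    flag (coverage > 0.9).
    """
    frames = []
    for condition in conditions:
        result = evaluate_coverage(condition, methods, level, n_jobs=n_jobs)
        frames.append(result.summary())
    table = pd.concat(frames, ignore_index=True)
    table["acceptable"] = table["coverage"] > ACCEPTABLE_COVERAGE
    return table


def bias_coverage_correlation(bias: Sequence[float], coverage: Sequence[float]) -> float:
    """Pearson correlation between per-condition mu-hat bias and coverage."""
    bias = np.asarray(bias, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if bias.shape != coverage.shape or bias.ndim != 1:
        raise ValueError("bias and coverage must be 1-d arrays of equal length")
    if bias.size < 3:
        raise ValueError("need at least 3 conditions")
    if np.std(bias) == 0 or np.std(coverage) == 0:
        raise ValueError("zero variance in bias or coverage series")
    return float(np.corrcoef(bias, coverage)[0, 1])


# ---------------------------------------------------------------------------
# Preset condition grids

HEATMAP_PI_C = (0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5)


def _grid(mu, tau, pi_c, k, reps, seed, sizes=None, variance_mode="estimated"):
    conditions = []
    for m in mu:
        for t in tau:
            for p in pi_c:
                for kk in k:
                    conditions.append(
                        SimCondition(
                            mu=m,
                            tau=t,
                            pi_c=p,
                            k=kk,
                            group_sizes=sizes,
                            reps=reps,
                            seed=seed,
                            variance_mode=variance_mode,
                        )
                    )
    return conditions


PRESETS = {
    # Simulation study 1: binomial tables, size pattern, estimated variances.
    "study1": dict(
        mu=(0.0, 0.25, 0.5, 0.75, 1.0),
        tau=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
        pi_c=(0.1, 0.3, 0.5),
        k=(5, 10, 20, 40, 160),
        reps=10_000,
    ),
    # The k grid used when reporting study 1 results.
    "study1_reported": dict(
        mu=(0.0,),
        tau=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
        pi_c=(0.1, 0.5),
        k=(5, 10, 40, 80, 160),
        reps=10_000,
    ),
    # Simulation study 2: constant size 30, exact variances available.
    "study2": dict(
        mu=(0.0,),
        tau=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
        pi_c=(0.1, 0.5),
        k=(5, 40, 160),
        reps=3_000,
        sizes=(30,),
        variance_mode="exact",
    ),
    # Coverage maps over (k, pi_c) at constant size 30.
    "heatmap_k_pi": dict(
        mu=(0.0,),
        tau=(0.0, 0.5),
        pi_c=HEATMAP_PI_C,
        k=(5, 10, 20, 40, 80, 160),
        reps=10_000,
        sizes=(30,),
    ),
    # Coverage maps over (size, pi_c) at k = 20.
    "heatmap_size_pi": dict(
        mu=(0.0,),
        tau=(0.0, 0.5),
        pi_c=HEATMAP_PI_C,
        k=(20,),
        reps=10_000,
        sizes=None,  # filled per size below
    ),
}

HEATMAP_SIZES = (15, 30, 80, 160, 320, 800)


def build_preset(name: str, reps: Optional[int] = None, seed: Optional[int] = None):
    """Instantiate a named preset grid as a list of conditions.

    ``reps`` overrides the full-scale repetition count for desk-scale
    runs; ``seed`` seeds every condition (each condition still spawns
    independent substreams per repetition).
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = dict(PRESETS[name])
    spec["reps"] = reps if reps is not None else spec["reps"]
    spec["seed"] = seed
    if name == "heatmap_size_pi":
        conditions = []
        for size in HEATMAP_SIZES:
            sub = dict(spec)
            sub["sizes"] = (size,)
            conditions.extend(_grid(**sub))
        return conditions
    return _grid(**spec)
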