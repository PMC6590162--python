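"""Synthetic meta-analysis generator.

Draws per-study true log odds ratios theta_i ~ N(mu, tau^2), converts
each to an experimental-arm event probability given the control-arm
probability, simulates binomial 2x2 tables, and assembles the
continuity-corrected effect estimates.  Two variance modes are
supported (the estimated per-table variance, or the enumeration-exact
true variance at the study's own event probabilities) plus an
``ideal_normal`` generator mode in which effect estimates are drawn
directly from the normal random-effects model with known variances --
the regime where both CI methods are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .effects import FrequencyTable2x2, log_odds_ratio
from .exact import exact_log_or_moments
from .tau2 import MetaSample

__all__ = [
    "SimCondition",
    "GeneratedMeta",
    "pi_experimental",
    "group_size_pattern",
    "simulate_meta",
]

#: Per-group sizes replicated k/5 times in the standard pattern.
SIZE_PATTERN = (30, 50, 100, 150, 300)


def pi_experimental(theta: float, pi_c: float) -> float:
    """Experimental-arm event probability implied by a log odds ratio.

    ``pi_e = pi_c e^theta / (1 - pi_c + pi_c e^theta)``; the log-odds
    difference between the arms then equals theta exactly.
    """
    if not 0 < pi_c < 1:
        raise ValueError("pi_c must be in (0, 1)")
    odds = pi_c / (1.0 - pi_c) * np.exp(theta)
    return float(odds / (1.0 + odds))


def group_size_pattern(k: int) -> tuple[int, ...]:
    """The (30, 50, 100, 150, 300) pattern, each size repeated k/5 times.

    Keeps the average per-group size constant across k.  k must be a
    positive multiple of 5; fixed-size designs use an explicit
    ``group_sizes`` override instead.
    """
    if k <= 0 or k % 5 != 0:
        raise ValueError(f"k must be a positive multiple of 5, got {k}")
    return tuple(size for size in SIZE_PATTERN for _ in range(k // 5))


@dataclass(frozen=True)
class SimCondition:
    """One simulation cell: generative parameters plus run bookkeeping."""

    mu: float
    tau: float
    pi_c: float
    k: int
    group_sizes: Optional[tuple[int, ...]] = None
    reps: int = 1
    seed: Optional[int] = None
    variance_mode: str = "estimated"  # estimated | exact
    generator_mode: str = "binomial"  # binomial | ideal_normal

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if not 0 < self.pi_c < 1:
            raise ValueError("pi_c must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.variance_mode not in ("estimated", "exact"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        if self.generator_mode not in ("binomial", "ideal_normal"):
            raise ValueError(f"unknown generator_mode {self.generator_mode!r}")
        if self.group_sizes is None:
            object.__setattr__(self, "group_sizes", group_size_pattern(self.k))
        else:
            sizes = tuple(int(n) for n in self.group_sizes)
            if len(sizes) == 1:
                sizes = sizes * self.k
            if len(sizes) != self.k:
                raise ValueError("group_sizes length must equal k")
            if any(n <= 0 for n in sizes):
                raise ValueError("group sizes must be positive")
            object.__setattr__(self, "group_sizes", sizes)

    @property
    def tau2(self) -> float:
        return self.tau**2

    def with_(self, **changes) -> "SimCondition":
        return replace(self, **changes)


@dataclass(frozen=True)
class GeneratedMeta:
    """One simulated meta-analysis: truths, raw tables, effect estimates."""

    theta: np.ndarray
    tables: Optional[tuple[FrequencyTable2x2, ...]]
    sample: MetaSample
    zero_cells: np.ndarray  # per-study zero-cell counts (all 0 in ideal mode)


def _ideal_sigma2(group_sizes: Sequence[int]) -> np.ndarray:
    # Known within-study variances for the ideal-normal mode; 8/n mirrors
    # the log-OR variance of a balanced table at event probability 0.5.
    return 8.0 / np.asarray(group_sizes, dtype=float)


def simulate_meta(condition: SimCondition, rng: np.random.Generator) -> GeneratedMeta:
    """Draw one meta-analysis under the condition's generative model."""
    k = condition.k
    theta = rng.normal(condition.mu, condition.tau, size=k)

    if condition.generator_mode == "ideal_normal":
        sigma2 = _ideal_sigma2(condition.group_sizes)
        y = rng.normal(condition.mu, np.sqrt(condition.tau2 + sigma2))
        sample = MetaSample(y=y, var=sigma2)
        return GeneratedMeta(
            theta=theta, tables=None, sample=sample, zero_cells=np.zeros(k, dtype=int)
        )

    sizes = np.asarray(condition.group_sizes)
    pi_e = np.array([pi_experimental(t, condition.pi_c) for t in theta])
    x_c = rng.binomial(sizes, condition.pi_c)
    x_e = rng.binomial(sizes, pi_e)
    tables = tuple(
        FrequencyTable2x2(int(xe), int(n), int(xc), int(n))
        for xe, xc, n in zip(x_e, x_c, sizes)
    )
    estimates = [log_odds_ratio(t) for t in tables]
    y = np.array([e.y for e in estimates])
    zero_cells = np.array([e.zero_cells for e in estimates], dtype=int)

    if condition.variance_mode == "exact":
        var = np.array(
            [
                exact_log_or_moments(int(n), int(n), float(pe), condition.pi_c).var_y
                for n, pe in zip(sizes, pi_e)
            ]
        )
    else:
        var = np.array([e.v for e in estimates])

    return GeneratedMeta(
        theta=theta, tables=tables, sample=MetaSample(y=y, var=var), zero_cells=zero_cells
    )
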