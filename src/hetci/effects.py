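"""Effect-size computation for 2x2 frequency tables.

Converts arm-level event counts into continuity-corrected log odds
ratios with estimated sampling variances.  The +0.5 correction is
applied to every cell of every table (not only tables with zero
cells), which keeps the log odds ratio and its variance finite and
reduces small-sample bias of the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FrequencyTable2x2",
    "EffectEstimate",
    "log_odds_ratio",
    "count_zero_cells",
]


@dataclass(frozen=True)
class FrequencyTable2x2:
    """Event counts of one two-arm study.

    Parameters
    ----------
    x_e : int
        Number of events in the experimental arm.
    n_e : int
        Size of the experimental arm.
    x_c : int
        Number of events in the control arm.
    n_c : int
        Size of the control arm.
    """

    x_e: int
    n_e: int
    x_c: int
    n_c: int

    def __post_init__(self) -> None:
        for name in ("x_e", "n_e", "x_c", "n_c"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                if not (isinstance(value, float) and value.is_integer()):
                    raise TypeError(f"{name} must be an integer, got {value!r}")
                object.__setattr__(self, name, int(value))
        if self.n_e <= 0 or self.n_c <= 0:
            raise ValueError("arm sizes must be positive")
        if not (0 <= self.x_e <= self.n_e):
            raise ValueError(f"x_e={self.x_e} outside [0, {self.n_e}]")
        if not (0 <= self.x_c <= self.n_c):
            raise ValueError(f"x_c={self.x_c} outside [0, {self.n_c}]")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """The four cell counts (x_e, n_e - x_e, x_c, n_c - x_c)."""
        return (self.x_e, self.n_e - self.x_e, self.x_c, self.n_c - self.x_c)

    def swapped(self) -> "FrequencyTable2x2":
        """Return the table with the arm labels exchanged."""
        return FrequencyTable2x2(self.x_c, self.n_c, self.x_e, self.n_e)


@dataclass(frozen=True)
class EffectEstimate:
    """A continuity-corrected log odds ratio with its estimated variance.

    Attributes
    ----------
    y : float
        Log odds ratio after adding 0.5 to every cell.
    v : float
        Estimated sampling variance (sum of reciprocal corrected cells);
        always finite and positive.
    zero_cells : int
        Number of zero cells (0-4) in the source table.
    """

    y: float
    v: float
    zero_cells: int = 0

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("sampling variance must be positive")
        if not 0 <= self.zero_cells <= 4:
            raise ValueError("zero_cells must be in 0..4")


def log_odds_ratio(table: FrequencyTable2x2) -> EffectEstimate:
    """Continuity-corrected log odds ratio and variance of one table.

    Adds 0.5 to each of the four cells, then computes

        y = log[(x_e+.5)(n_c-x_c+.5) / ((n_e-x_e+.5)(x_c+.5))]
        v = 1/(x_e+.5) + 1/(n_e-x_e+.5) + 1/(x_c+.5) + 1/(n_c-x_c+.5)

    The correction is unconditional, so y and v exist for every valid
    table including those with zero cells.
    """
    a, b, c, d = (cell + 0.5 for cell in table.cells)
    y = math.log(a * d / (b * c))
    v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectEstimate(y=y, v=v, zero_cells=count_zero_cells(table))


def count_zero_cells(table: FrequencyTable2x2) -> int:
    """Number of zero cells among x_e, n_e - x_e, x_c, n_c - x_c."""
    return sum(1 for cell in table.cells if cell == 0)
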