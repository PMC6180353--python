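"""Pearson chi-square statistic and a leakage-aware survival function.

The association test compares, for one SNP, presence counts between the
control and case cohorts.  With n_ctrl / n_case presence counts and
N_ctrl / N_case twice the number of files per cohort (a homozygous
carrier contributes 2, heterozygous 1, so each file contributes at most
2), the pooled frequency is f = (n_ctrl + n_case) / (N_ctrl + N_case)
and the statistic is the classic sum of (O - E)^2 / E over the four
cells

    O = [n_ctrl, n_case, N_ctrl - n_ctrl, N_case - n_case]
    E = [N_ctrl f, N_case f, N_ctrl (1 - f), N_case (1 - f)]

which equals the standard 2x2 Pearson statistic
N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with 1 degree of freedom.

P-values come from the df=1 chi-square survival function.  To keep the
memory access pattern independent of the (secret) statistic value, the
survival function is evaluated from a precomputed grid: every query
scans the whole grid with branch-free selection of the bracketing cell
and then runs a trapezoidal refinement with a fixed number of steps.
The integration works in the transformed variable t = sqrt(x), where
the df=1 density becomes the half-normal density
sqrt(2/pi) * exp(-t^2 / 2) and the x^(-1/2) singularity at zero
disappears.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "chi2_statistic",
    "SurvivalTable",
    "DEFAULT_X_MAX",
    "DEFAULT_N_GRID",
    "DEFAULT_REFINE_STEPS",
]

DEFAULT_X_MAX = 64.0  # survival(64) ~ 1e-15: below any ranking difference
DEFAULT_N_GRID = 1024
DEFAULT_REFINE_STEPS = 32

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def chi2_statistic(
    n_ctrl: float, n_case: float, N_ctrl: float, N_case: float
) -> float:
    """Pearson chi-square statistic of the 2x2 presence table.

    Accepts real-valued counts (expected counts are used by the
    synthetic-data truth table).  Returns 0 for the degenerate pooled
    frequencies f in {0, 1}, where the table carries no discriminative
    information.  Raises ValueError outside 0 <= n <= N or for
    non-positive totals.
    """
    if N_ctrl <= 0 or N_case <= 0:
        raise ValueError("cohort totals must be positive")
    if not (0 <= n_ctrl <= N_ctrl and 0 <= n_case <= N_case):
        raise ValueError(
            f"counts out of range: {n_ctrl}/{N_ctrl}, {n_case}/{N_case}"
        )
    f = (n_ctrl + n_case) / (N_ctrl + N_case)
    if f == 0.0 or f == 1.0:
        return 0.0
    observed = (n_ctrl, n_case, N_ctrl - n_ctrl, N_case - n_case)
    expected = (N_ctrl * f, N_case * f, N_ctrl * (1.0 - f), N_case * (1.0 - f))
    return float(
        sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    )


def _half_normal(t: np.ndarray | float) -> np.ndarray | float:
    """Density of |Z| for standard normal Z; df=1 chi-square in t=sqrt(x)."""
    return _SQRT_2_OVER_PI * np.exp(-0.5 * np.square(t))


class SurvivalTable:
    """Precomputed df=1 chi-square survival function with oblivious lookup.

    The grid holds ``n_grid`` equally spaced points on [0, x_max]; grid
    values are computed once by fine trapezoidal integration of the
    half-normal density, with S(0) = 1 exactly.  A query refines from
    the nearest grid point (in t = sqrt(x)) with exactly
    ``refine_steps`` trapezoid sub-steps whatever the input, and the
    sequence of table positions touched is the same for every
    x in [0, x_max]; x above x_max returns the tail value at x_max.

    Set ``instrument=True`` to record the touched positions of each
    query in ``access_log`` (a list of per-query position tuples) —
    used to test the data-independent access contract.
    """

    def __init__(
        self,
        x_max: float = DEFAULT_X_MAX,
        n_grid: int = DEFAULT_N_GRID,
        refine_steps: int = DEFAULT_REFINE_STEPS,
        construction_substeps: int = 1024,
        instrument: bool = False,
    ):
        if x_max <= 0:
            raise ValueError(f"x_max must be positive, got {x_max}")
        if n_grid < 2:
            raise ValueError(f"n_grid must be >= 2, got {n_grid}")
        if refine_steps < 1:
            raise ValueError(f"refine_steps must be >= 1, got {refine_steps}")
        self.x_max = float(x_max)
        self.n_grid = int(n_grid)
        self.refine_steps = int(refine_steps)
        self.grid_x = np.linspace(0.0, self.x_max, self.n_grid)
        self._grid_t = np.sqrt(self.grid_x)
        self.values = self._tabulate(construction_substeps)
        self.instrument = instrument
        self.access_log: list[tuple[tuple[str, int], ...]] = []

    def _tabulate(self, substeps: int) -> np.ndarray:
        """Trapezoidal integration cell by cell in t-space.

        Values are accumulated from the tail upward (plus the mass
        beyond x_max, integrated far enough that the remainder is below
        float underflow) so the deep tail keeps full relative precision
        — a plain 1 - cumsum would flatten below ~1e-9 through
        cancellation.  The result is normalized so S(0) is exactly 1.
        """
        t = self._grid_t
        cell_integrals = np.empty(self.n_grid - 1)
        for k in range(self.n_grid - 1):
            sub = np.linspace(t[k], t[k + 1], substeps + 1)
            cell_integrals[k] = np.trapezoid(_half_normal(sub), sub)
        t_max = t[-1]
        beyond = np.linspace(t_max, t_max + 12.0, 16 * substeps + 1)
        tail = np.trapezoid(_half_normal(beyond), beyond)
        values = np.empty(self.n_grid)
        values[-1] = tail
        values[:-1] = tail + np.cumsum(cell_integrals[::-1])[::-1]
        return values / values[0]

    def survival(self, x: float) -> float:
        """P(X >= x) for X chi-square distributed with 1 df.

        Data-independent evaluation: two full scans of the grid (index
        location, then branch-free value selection) and a fixed-length
        trapezoidal refinement.
        """
        if x < 0:
            raise ValueError(f"survival is defined for x >= 0, got {x}")
        xc = min(float(x), self.x_max)
        n = self.n_grid
        grid_x = self.grid_x
        grid_t = self._grid_t
        values = self.values
        log: list[tuple[str, int]] = []

        # pass 1: index of the last grid point <= xc, touching every cell
        idx = 0
        for k in range(n):
            log.append(("grid", k))
            idx += int(grid_x[k] <= xc)
        idx -= 1
        kup = idx + int(idx + 1 < n)  # upper neighbour, clamped at the end

        # pass 2: branch-free selection of both bracketing entries
        v_lo = 0.0
        v_hi = 0.0
        t_lo = 0.0
        t_hi = 0.0
        for k in range(n):
            log.append(("sf", k))
            sel_lo = int(k == idx)
            sel_hi = int(k == kup)
            v_lo += sel_lo * values[k]
            v_hi += sel_hi * values[k]
            t_lo += sel_lo * grid_t[k]
            t_hi += sel_hi * grid_t[k]

        # integrate from the nearer endpoint in t; sign selected branch-free
        tq = math.sqrt(xc)
        use_hi = int((t_hi - tq) < (tq - t_lo))
        base = use_hi * v_hi + (1 - use_hi) * v_lo
        t0 = use_hi * t_hi + (1 - use_hi) * t_lo
        h = (tq - t0) / self.refine_steps
        acc = 0.5 * (
            _half_normal(t0) + _half_normal(t0 + self.refine_steps * h)
        )
        for j in range(1, self.refine_steps):
            acc += _half_normal(t0 + j * h)
        integral = acc * h  # signed: negative when integrating downward
        result = float(min(1.0, max(0.0, base - integral)))

        if self.instrument:
            self.access_log.append(tuple(log))
        return result

    __call__ = survival
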