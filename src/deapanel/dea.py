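"""Output-oriented BCC (variable-returns-to-scale) data envelopment analysis.

Each decision-making unit (DMU) converts a vector of inputs ``x`` into a
vector of outputs ``y``.  The Farrell output distance of DMU *o* is the
value of the envelopment linear program

    max theta
    s.t.  Y' lam >= theta * y_o
          X' lam <= x_o
          sum(lam) = 1        (VRS only; dropped under CRS)
          lam >= 0

``theta >= 1`` always (the DMU envelops itself), and the reported
technical-efficiency score is the reciprocal ``1/theta`` in ``(0, 1]``,
with 1 meaning the DMU lies on the estimated frontier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: tolerance used when checking LP feasibility / clipping theta
FEAS_TOL = 1e-9


@dataclass
class DeaProblem:
    """One cross-section of DMUs: inputs ``X`` (n x p), outputs ``Y`` (n x q)."""

    X: np.ndarray
    Y: np.ndarray
    returns_to_scale: str = "vrs"
    orientation: str = "output"
    year: int | None = None
    dmu_ids: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows (DMUs)")
        if self.X.shape[0] < 1:
            raise ValueError("need at least one DMU")
        if self.returns_to_scale not in ("vrs", "crs"):
            raise ValueError(f"unknown returns_to_scale {self.returns_to_scale!r}")
        if self.orientation != "output":
            raise ValueError("only output orientation is supported")
        if np.any(self.X < 0) or np.any(self.Y < 0):
            raise ValueError("inputs and outputs must be non-negative")
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.Y)):
            raise ValueError("inputs and outputs must be finite")
        if np.any((self.Y <= 0).all(axis=1)):
            raise ValueError("every DMU needs at least one positive output")
        if np.any((self.X <= 0).all(axis=0)):
            raise ValueError(
                "every input column needs at least one positive entry "
                "(drop all-zero columns before building the problem)"
            )
        if self.dmu_ids is None:
            self.dmu_ids = list(range(self.n_dmus))

    @property
    def n_dmus(self) -> int:
        return self.X.shape[0]


@dataclass
class DeaScore:
    dmu_id: object
    theta: float  # Farrell output distance, >= 1
    efficiency: float  # 1 / theta, in (0, 1]
    lam: np.ndarray = field(repr=False, default=None)


def _solve_envelopment(
    X: np.ndarray,
    Y: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    vrs: bool,
    theta_lower: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Solve max theta s.t. Y'lam >= theta*y0, X'lam <= x0, [sum lam = 1].

    The reference technology is spanned by the rows of (X, Y); the
    evaluated point (x0, y0) need not be one of them (the bootstrap
    evaluates original units against a pseudo reference set).
    """
    n, p = X.shape
    q = Y.shape[1]
    c = np.zeros(n + 1)
    c[0] = -1.0  # maximize theta
    A_ub = np.zeros((q + p, n + 1))
    b_ub = np.zeros(q + p)
    A_ub[:q, 0] = y0
    A_ub[:q, 1:] = -Y.T  # theta*y0 - Y'lam <= 0
    A_ub[q:, 1:] = X.T  # X'lam <= x0
    b_ub[q:] = x0
    if vrs:
        A_eq = np.zeros((1, n + 1))
        A_eq[0, 1:] = 1.0
        b_eq = np.array([1.0])
    else:
        A_eq, b_eq = None, None
    bounds = [(theta_lower, None)] + [(0.0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        # rescale columns to unit mean and retry once
        sx = np.where(X.mean(axis=0) > 0, X.mean(axis=0), 1.0)
        sy = np.where(Y.mean(axis=0) > 0, Y.mean(axis=0), 1.0)
        A_ub2 = A_ub.copy()
        b_ub2 = b_ub.copy()
        A_ub2[:q, 0] = y0 / sy
        A_ub2[:q, 1:] = -(Y / sy).T
        A_ub2[q:, 1:] = (X / sx).T
        b_ub2[q:] = x0 / sx
        res = linprog(c, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if not res.success:
            raise RuntimeError(
                f"envelopment LP failed after rescaling retry: {res.message}"
            )
    return -res.fun, np.asarray(res.x[1:])


def farrell_output_distance(problem: DeaProblem, dmu_index: int) -> DeaScore:
    """Farrell output distance theta >= 1 of one DMU within its cross-section."""
    if not 0 <= dmu_index < problem.n_dmus:
        raise IndexError(f"dmu_index {dmu_index} out of range")
    vrs = problem.returns_to_scale == "vrs"
    theta, lam = _solve_envelopment(
        problem.X, problem.Y, problem.X[dmu_index], problem.Y[dmu_index],
        vrs=vrs, theta_lower=1.0 if vrs else 0.0,
    )
    theta = max(theta, 1.0)  # self-envelopment guarantees theta >= 1
    return DeaScore(
        dmu_id=problem.dmu_ids[dmu_index],
        theta=theta,
        efficiency=1.0 / theta,
        lam=lam,
    )


def solve_problem(problem: DeaProblem) -> list[DeaScore]:
    """Score every DMU of a cross-section."""
    return [farrell_output_distance(problem, i) for i in range(problem.n_dmus)]


def problem_from_frame(
    frame: pd.DataFrame,
    input_cols: list[str],
    output_cols: list[str],
    id_col: str = "jurisdiction_id",
    returns_to_scale: str = "vrs",
    year: int | None = None,
) -> DeaProblem:
    """Build a :class:`DeaProblem` from a panel slice, dropping all-zero input columns.

    Input columns that are entirely zero in this cross-section carry no
    constraint and destabilise the solver; they are dropped with a warning.
    """
    missing = [c for c in input_cols + output_cols if c not in frame.columns]
    if missing:
        raise KeyError(f"columns absent from frame: {missing}")
    sub = frame[input_cols + output_cols]
    if sub.isna().any().any():
        bad = frame.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in rows {bad}")
    keep = [c for c in input_cols if (frame[c] > 0).any()]
    dropped = sorted(set(input_cols) - set(keep))
    if dropped:
        logger.warning(
            "year %s: dropping all-zero input columns %s", year, dropped
        )
    return DeaProblem(
        X=frame[keep].to_numpy(float),
        Y=frame[output_cols].to_numpy(float),
        returns_to_scale=returns_to_scale,
        year=year,
        dmu_ids=frame[id_col].tolist() if id_col in frame.columns else None,
    )


def score_year(
    frame: pd.DataFrame,
    input_cols: list[str],
    output_cols: list[str],
    id_col: str = "jurisdiction_id",
    returns_to_scale: str = "vrs",
    year: int | None = None,
) -> pd.DataFrame:
    """Score one calendar-year cross-section; returns a tidy per-DMU table.

    At least one DMU always attains efficiency 1 (the frontier is never
    empty under self-envelopment).
    """
    if len(frame) < 2:
        raise ValueError("need at least 2 DMUs to estimate a frontier")
    problem = problem_from_frame(
        frame, input_cols, output_cols, id_col=id_col,
        returns_to_scale=returns_to_scale, year=year,
    )
    scores = solve_problem(problem)
    if year is None and "year" in frame.columns:
        year_vals = frame["year"].to_numpy()
    else:
        year_vals = year
    out = pd.DataFrame(
        {
            "jurisdiction_id": [s.dmu_id for s in scores],
            "year": year_vals,
            "theta": [s.theta for s in scores],
            "efficiency": [s.efficiency for s in scores],
        }
    )
    n_p = problem.X.shape[1] + problem.Y.shape[1]
    if len(frame) < 3 * n_p:
        logger.warning(
            "year %s: %d DMUs for %d dimensions violates the n >= 3(p+q) "
            "rule of thumb; scores may be inflated", year, len(frame), n_p,
        )
    return out
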