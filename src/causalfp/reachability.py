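"""Reachability landscape: per-region maximal activation under bounded input.

Rewriting the implicit model in state-evolution form

    x(t) = A_hat x(t-1) + B1_hat u(t) + B2_hat u(t-1),
    A_hat = (I-Q)^{-1} A,  B1_hat = (I-Q)^{-1} B1,  B2_hat = (I-Q)^{-1} B2,

the terminal state from rest (x(0)=0) is linear in the stacked input
sequence: x(T_M) = sum_k M_k u(k) with

    M_k = [k >= 1] A_hat^{T_M-k} B1_hat + A_hat^{T_M-1-k} B2_hat,
    k = 0..T_M-1,  u(T_M) = 0.

Maximizing each entry of x(T_M) decouples by region. Under the energy
model (vectorized l2 ball, ||U||_F <= 1) the maximum of region i is the
l2 norm of row i of [M_0 ... M_{T_M-1}], attained by the unit input
sequence aligned with that row. Under the box model (|u| <= 1 entrywise,
the linear-programming reading) it is the l1 norm of the same row.

Values are displayed as a 12 x 12 heatmap grid: the m regions fill cells
row-major in atlas order, remaining cells masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import CausalSignature, _solve_implicit

__all__ = [
    "StateEvolutionForm",
    "ReachabilityLandscape",
    "to_state_evolution_form",
    "reachability_values",
    "input_response_matrix",
    "landscape_grid",
]

GRID_SIDE = 12


@dataclass
class StateEvolutionForm:
    """Explicit recursion equivalent to the implicit two-timescale model."""

    A_hat: np.ndarray
    B1_hat: np.ndarray
    B2_hat: np.ndarray

    def __post_init__(self) -> None:
        for name in ("A_hat", "B1_hat", "B2_hat"):
            M = np.asarray(getattr(self, name), dtype=float)
            if not np.isfinite(M).all():
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, M)
        m = self.A_hat.shape[0]
        if self.A_hat.shape != (m, m):
            raise ValueError("A_hat must be square")
        if self.B1_hat.shape[0] != m or self.B1_hat.shape != self.B2_hat.shape:
            raise ValueError("B1_hat/B2_hat must be m x n with matching shapes")

    @property
    def m(self) -> int:
        return self.A_hat.shape[0]

    @property
    def n(self) -> int:
        return self.B1_hat.shape[1]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A_hat))))

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass
class ReachabilityLandscape:
    """Per-region maximal terminal activations with 12x12 grid layout."""

    values: np.ndarray
    horizon: int
    norm_model: str
    grid: np.ma.MaskedArray
    normalization: str

    @property
    def m(self) -> int:
        return self.values.size


def to_state_evolution_form(sig: CausalSignature) -> StateEvolutionForm:
    """Fold the fast concurrent block into the state evolution.

    Computed by linear solve against (I - Q); raises when (I - Q) is
    numerically singular (condition number >= 1e12, reported).
    """
    inv = _solve_implicit(sig.Q)
    return StateEvolutionForm(
        A_hat=inv @ sig.A, B1_hat=inv @ sig.B1, B2_hat=inv @ sig.B2
    )


def simulate_explicit(
    form: StateEvolutionForm, U: np.ndarray, x0: np.ndarray
) -> np.ndarray:
    """Run the explicit recursion; returns the m x (T+1) state matrix."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    T = U.shape[1] - 1
    X = np.empty((form.m, T + 1))
    X[:, 0] = np.asarray(x0, dtype=float).reshape(form.m)
    for t in range(1, T + 1):
        X[:, t] = (
            form.A_hat @ X[:, t - 1]
            + form.B1_hat @ U[:, t]
            + form.B2_hat @ U[:, t - 1]
        )
    return X


def input_response_matrix(form: StateEvolutionForm, T_M: int) -> np.ndarray:
    """Stacked response [M_0 ... M_{T_M-1}] mapping inputs to x(T_M).

    Powers of A_hat are accumulated iteratively (no eigendecomposition).
    """
    if T_M < 1 or int(T_M) != T_M:
        raise ValueError(f"horizon must be a positive integer, got {T_M}")
    T_M = int(T_M)
    m, n = form.m, form.n
    blocks = [np.zeros((m, n)) for _ in range(T_M)]
    # walk k from T_M-1 down to 0 while power counts up
    Apow = np.eye(m)  # A_hat^0
    for k in range(T_M - 1, -1, -1):
        # M_k = [k>=1] A_hat^{T_M-k} B1_hat + A_hat^{T_M-1-k} B2_hat
        blocks[k] = blocks[k] + Apow @ form.B2_hat  # exponent T_M-1-k
        Apow_next = form.A_hat @ Apow  # exponent T_M-k
        if k >= 1:
            blocks[k] = blocks[k] + Apow_next @ form.B1_hat
        Apow = Apow_next
    return np.hstack(blocks) if n else np.zeros((m, 0))


def reachability_values(
    form: StateEvolutionForm, T_M: int, norm_model: str = "energy"
) -> np.ndarray:
    """Maximal terminal activation of each region from rest.

    ``norm_model="energy"`` bounds the vectorized input energy
    (``||U||_F <= 1``) and returns the row-wise l2 norms of the stacked
    response matrix; ``"box"`` bounds every input entry (``|u| <= 1``) and
    returns row-wise l1 norms. Box values dominate energy values entrywise
    and both are non-negative.

    Values are non-decreasing in ``T_M`` when ``B1_hat = 0`` (every input
    acts with a one-step lag, so a longer horizon can replay any shorter
    input schedule shifted in time). With a concurrent channel
    ``B1_hat != 0`` this nesting breaks at the first step — ``u(0)`` acts
    only through the lagged gain because ``x(0)`` is pinned to rest — and
    the maximum can genuinely dip as the horizon grows.
    """
    if norm_model not in ("energy", "box"):
        raise ValueError(f"norm_model must be 'energy' or 'box', got {norm_model!r}")
    M = input_response_matrix(form, T_M)
    if M.shape[1] == 0:
        return np.zeros(form.m)
    if norm_model == "energy":
        return np.linalg.norm(M, axis=1)
    return np.abs(M).sum(axis=1)


def landscape_grid(
    values: np.ndarray,
    normalization: str = "minmax",
    horizon: int = 1,
    norm_model: str = "energy",
) -> ReachabilityLandscape:
    """Lay region values onto the 12x12 heatmap grid in atlas order.

    Min-max normalization by default (max -> 1, min -> 0; a constant
    vector maps to all ones). Cells beyond the m regions are masked.
    """
    values = np.asarray(values, dtype=float).ravel()
    m = values.size
    if m > GRID_SIDE * GRID_SIDE:
        raise ValueError(
            f"{m} regions do not fit the {GRID_SIDE}x{GRID_SIDE} layout"
        )
    if normalization == "minmax":
        lo, hi = values.min(), values.max()
        norm = np.ones_like(values) if hi == lo else (values - lo) / (hi - lo)
    elif normalization == "none":
        norm = values.copy()
    else:
        raise ValueError(f"normalization must be 'minmax' or 'none', got {normalization!r}")

    flat = np.zeros(GRID_SIDE * GRID_SIDE)
    mask = np.ones(GRID_SIDE * GRID_SIDE, dtype=bool)
    flat[:m] = norm
    mask[:m] = False
    grid = np.ma.MaskedArray(
        flat.reshape(GRID_SIDE, GRID_SIDE), mask=mask.reshape(GRID_SIDE, GRID_SIDE)
    )
    return ReachabilityLandscape(
        values=values,
        horizon=int(horizon),
        norm_model=norm_model,
        grid=grid,
        normalization=normalization,
    )


def grid_to_values(landscape: ReachabilityLandscape) -> np.ndarray:
    """Invert the grid placement, recovering the normalized vector in atlas order."""
    flat = landscape.grid.data.ravel()
    mask = landscape.grid.mask.ravel()
    return flat[~mask]
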