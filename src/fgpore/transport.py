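"""Closed-form transport model G(D, n) = f(D') - g(X).

f(D') = a1 D'^2 with D' = D/L captures the quadratic growth of the barrier
with cargo size; g(X) = b2 X^2 + b1 X + b0 with X = n a / (pi D) captures
the barrier reduction from hydrophobic binding spots.  The coefficients are
always fitted to simulated barrier tables; classification against the
thermal energy kBT separates expelled, transported and trapped regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import KBT_300

__all__ = [
    "TransportModelParams",
    "hydrophobic_measure",
    "fit_f",
    "fit_g",
    "predict_G",
    "transport_regime",
    "energy_map",
]


@dataclass
class TransportModelParams:
    """Fitted coefficients plus geometric constants of the model."""

    a1: float = 0.0
    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    L: float = 60.0
    a: float = 0.6
    kBT: float = KBT_300
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.L <= 0 or self.a <= 0:
            raise ValueError("L and a must be positive")


def hydrophobic_measure(n: int, D: float, a: float = 0.6) -> float:
    """Hydrophobic contact-area measure X = n a / (pi D)."""
    if D <= 0:
        raise ValueError("D must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * a / (np.pi * D)


def fit_f(
    table: pd.DataFrame | np.ndarray,
    L: float = 60.0,
    weights: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Least-squares a1 for G = a1 (D/L)^2 on an inert-cargo (D, G) table.

    Returns (a1, diagnostics) with per-point residuals.
    """
    arr = np.asarray(table[["D", "G"]] if isinstance(table, pd.DataFrame) else table, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two (D, G) points")
    d2 = (arr[:, 0] / L) ** 2
    g = arr[:, 1]
    w = np.ones_like(g) if weights is None else np.asarray(weights, dtype=float)
    a1 = float(np.sum(w * d2 * g) / np.sum(w * d2 * d2))
    resid = g - a1 * d2
    diag = {
        "residuals": resid,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "n_points": int(arr.shape[0]),
    }
    return a1, diag


def fit_g(
    table: pd.DataFrame | np.ndarray,
    a1: float,
    D: float,
    L: float = 60.0,
    a: float = 0.6,
    constrain_b0_zero: bool = False,
    weights: np.ndarray | None = None,
) -> tuple[tuple[float, float, float], dict]:
    """Least-squares quadratic g(X) = b2 X^2 + b1 X + b0 at fixed diameter.

    The table holds (n, G) at diameter ``D``; the fit target is
    g = f(D/L) - G against X = n a / (pi D).  Returns ((b0, b1, b2), diag).
    """
    arr = np.asarray(table[["n", "G"]] if isinstance(table, pd.DataFrame) else table, dtype=float)
    min_pts = 2 if constrain_b0_zero else 3
    if arr.shape[0] < min_pts:
        raise ValueError(f"need at least {min_pts} (n, G) points")
    x = np.array([hydrophobic_measure(int(n), D, a) for n in arr[:, 0]])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: all X values equal")
    y = a1 * (D / L) ** 2 - arr[:, 1]
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if constrain_b0_zero:
        A = np.column_stack([x, x**2])
    else:
        A = np.column_stack([np.ones_like(x), x, x**2])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    b = (0.0, float(coef[0]), float(coef[1])) if constrain_b0_zero else tuple(float(c) for c in coef)
    resid = y - A @ coef
    diag = {
        "residuals": resid,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "X": x,
        "n_points": int(arr.shape[0]),
    }
    return b, diag  # type: ignore[return-value]


def predict_G(D: float, n: int, params: TransportModelParams) -> float:
    """G(D, n) = a1 (D/L)^2 - (b2 X^2 + b1 X + b0)."""
    x = hydrophobic_measure(n, D, params.a)
    f = params.a1 * (D / params.L) ** 2
    g = params.b2 * x**2 + params.b1 * x + params.b0
    return float(f - g)


def transport_regime(G: float, kBT: float = KBT_300) -> str:
    """Classify: G > +kBT expelled; |G| <= kBT transported; G < -kBT trapped."""
    if not np.isfinite(G):
        raise ValueError("G must be finite")
    if G > kBT:
        return "expelled"
    if G < -kBT:
        return "trapped"
    return "transported"


def energy_map(
    D_grid: np.ndarray,
    n_grid: np.ndarray,
    params: TransportModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """G and regime labels on a (D, n) grid; rows index n, columns index D."""
    D_grid = np.asarray(D_grid, dtype=float)
    n_grid = np.asarray(n_grid)
    if np.any(D_grid <= 0) or np.any(n_grid < 0):
        raise ValueError("grids must be positive (D) and non-negative (n)")
    G = np.empty((len(n_grid), len(D_grid)))
    for i, n in enumerate(n_grid):
        for j, d in enumerate(D_grid):
            G[i, j] = predict_G(float(d), int(n), params)
    labels = np.empty_like(G, dtype=object)
    labels[G > params.kBT] = "expelled"
    labels[G < -params.kBT] = "trapped"
    labels[(G >= -params.kBT) & (G <= params.kBT)] = "transported"
    return G, labels
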