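"""Sensitivity of equilibrium dSSB to fishing intensity and carrying capacity.

The long-run biomass of the harvested logistic map at fixed forcing is
X(alpha, K) = max(0, K (1 - alpha/r)). Over a regular grid in alpha (0–0.5)
and K (0–1), both with step theta = 0.001, central differences give the two
sensitivities zeta = |dX/dalpha| and eta = |dX/dK|; their elementwise sum I
is min-max standardised to I* in [0, 1]. At the kink alpha = r where the
floor engages, one-sided differences are used so the surface does not show a
spurious spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import simulate

DEFAULT_THETA = 0.001


@dataclass
class SensitivityGrids:
    """Equilibrium surface and its standardised joint sensitivity.

    Rows index K, columns index alpha. ``zeta`` and ``eta`` are NaN on the
    boundary nodes where a central difference is undefined.
    """

    alpha_axis: np.ndarray
    k_axis: np.ndarray
    x_surface: np.ndarray
    zeta: np.ndarray
    eta: np.ndarray
    i_raw: np.ndarray
    i_star: np.ndarray


def make_axes(theta: float = DEFAULT_THETA,
              alpha_max: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Regular alpha in [0, alpha_max] and K in [0, 1] grids with step theta."""
    alpha = np.arange(0.0, alpha_max + theta / 2, theta)
    k = np.arange(0.0, 1.0 + theta / 2, theta)
    return alpha, k


def dssb_surface(r: float, alpha_axis, k_axis,
                 mode: str = "equilibrium", x0: float = 0.5,
                 horizon: int = 200) -> np.ndarray:
    """dSSB at each (K, alpha) node.

    ``equilibrium`` (default) uses the closed-form fixed point
    K (1 - alpha/r) floored at 0; ``transient`` iterates the map for
    ``horizon`` years from ``x0`` and reports the final state.
    """
    a = np.asarray(alpha_axis, dtype=float)
    k = np.asarray(k_axis, dtype=float)
    if mode == "equilibrium":
        return np.maximum(0.0, k[:, None] * (1.0 - a[None, :] / r))
    if mode == "transient":
        out = np.empty((len(k), len(a)))
        for i, kk in enumerate(k):
            for j, aa in enumerate(a):
                if kk == 0:
                    out[i, j] = 0.0
                    continue
                traj = simulate(x0, np.full(horizon, kk), aa, r)
                out[i, j] = traj.x[-1]
        return out
    raise ValueError(f"unknown surface mode {mode!r}")


def _diff_along(x: np.ndarray, axis_vals: np.ndarray, axis: int,
                kink_at: float | None) -> np.ndarray:
    """|central difference| along one axis; one-sided across a kink.

    Boundary nodes are NaN. If ``kink_at`` is given, interior nodes whose
    central stencil straddles that axis value take the one-sided difference
    on their own side of the kink.
    """
    v = np.asarray(axis_vals, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least three nodes for central differences")
    if np.ptp(v) == 0:
        raise ValueError("degenerate axis")
    x = np.moveaxis(x, axis, -1)
    out = np.full_like(x, np.nan, dtype=float)
    central = np.abs(x[..., 2:] - x[..., :-2]) / np.abs(v[2:] - v[:-2])
    out[..., 1:-1] = central
    if kink_at is not None:
        for i in range(1, len(v) - 1):
            if v[i - 1] < kink_at < v[i + 1]:
                if v[i] <= kink_at:
                    out[..., i] = np.abs(x[..., i] - x[..., i - 1]) / abs(v[i] - v[i - 1])
                else:
                    out[..., i] = np.abs(x[..., i + 1] - x[..., i]) / abs(v[i + 1] - v[i])
    return np.moveaxis(out, -1, axis)


def zeta_grid(x_surface, alpha_axis, r: float | None = None) -> np.ndarray:
    """Sensitivity of dSSB to fishing intensity, |dX/dalpha|, per (K, alpha)."""
    return _diff_along(np.asarray(x_surface, dtype=float),
                       alpha_axis, axis=1, kink_at=r)


def eta_grid(x_surface, k_axis) -> np.ndarray:
    """Sensitivity of dSSB to carrying capacity, |dX/dK|, per (K, alpha)."""
    return _diff_along(np.asarray(x_surface, dtype=float),
                       k_axis, axis=0, kink_at=None)


def joint_sensitivity(zeta, eta) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise sum of the two sensitivities and its [0, 1] rescaling."""
    zeta = np.asarray(zeta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if zeta.shape != eta.shape:
        raise ValueError("zeta and eta grids must be congruent")
    i_raw = zeta + eta
    lo, hi = np.nanmin(i_raw), np.nanmax(i_raw)
    if hi == lo:
        raise ValueError("degenerate standardisation: joint sensitivity is constant")
    return i_raw, (i_raw - lo) / (hi - lo)


def sensitivity_analysis(r: float = 0.5, theta: float = DEFAULT_THETA,
                         alpha_max: float = 0.5,
                         mode: str = "equilibrium") -> SensitivityGrids:
    """Full surface-and-sensitivity computation at the standard grid."""
    alpha_axis, k_axis = make_axes(theta, alpha_max)
    x = dssb_surface(r, alpha_axis, k_axis, mode=mode)
    zeta = zeta_grid(x, alpha_axis, r=r)
    eta = eta_grid(x, k_axis)
    i_raw, i_star = joint_sensitivity(zeta, eta)
    return SensitivityGrids(alpha_axis=alpha_axis, k_axis=k_axis, x_surface=x,
                            zeta=zeta, eta=eta, i_raw=i_raw, i_star=i_star)
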