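"""Diffusion-based density-equalizing transform of the trained node lattice.

Each lattice node is treated as a unit-area square whose top-left corner
sits at its grid position, carrying its error-surface value as population
density.  The density field is let to diffuse to uniformity and every
point is advected along the velocity field v = -grad(rho)/rho; regions of
high density (cluster boundaries) inflate and low-density regions
(cluster interiors) contract, so implicit map structure becomes explicit
spatial aggregation.  The diffusion equation is solved spectrally with a
type-II discrete cosine transform, which imposes reflective (zero-flux)
boundaries, on a power-of-two grid.

A uniform density field yields the identity transform exactly: all
non-constant modes vanish, so the velocity is zero everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn

from .som import SOMState, ErrorSurface


@dataclass
class DensityGrid:
    """Rasterized density field plus the node squares to advect.

    ``density`` is a resolution x resolution non-negative field; background
    ("sea") cells not covered by any node square carry the mean node
    density.  ``node_corners`` holds, per node, its 4 square corners in
    grid units, ordered clockwise from the top-left.
    """

    resolution: int
    density: np.ndarray
    node_corners: np.ndarray  # (m, 4, 2) as (row, col) grid coordinates
    scale: int                # grid cells per lattice unit


@dataclass
class EqualizedCoordinates:
    """Density-equalized node positions (centroids of displaced squares)."""

    coords: np.ndarray          # (m, 2) equalized node centers
    corners: np.ndarray         # (m, 4, 2) displaced square corners
    original_coords: np.ndarray  # (m, 2) pre-transform square centers


def _is_pow2(x: int) -> bool:
    return x >= 1 and (x & (x - 1)) == 0


def build_density_grid(
    state: SOMState,
    surface: ErrorSurface,
    resolution: int = 64,
) -> DensityGrid:
    """Rasterize node unit squares onto a power-of-two density grid.

    The lattice is uniformly scaled by the largest integer factor that fits
    in ``resolution``; every cell covered by node j's square gets density
    En_j, uncovered cells get the mean node density, and a small floor
    keeps the diffusion field well-posed where En = 0.
    """
    if not _is_pow2(resolution):
        raise ValueError(f"resolution must be a power of 2, got {resolution}")
    side = state.side
    scale = resolution // side
    if scale < 1:
        raise ValueError(
            f"lattice side {side} exceeds resolution {resolution}; "
            "use a higher cartogram resolution"
        )
    En = np.asarray(surface.En, dtype=float)
    sea = En.mean()
    density = np.full((resolution, resolution), sea, dtype=float)
    m = state.n_nodes
    corners = np.empty((m, 4, 2), dtype=float)
    for j in range(m):
        r, c = state.grid_coords[j]
        r0, c0 = int(r) * scale, int(c) * scale
        density[r0:r0 + scale, c0:c0 + scale] = En[j]
        corners[j] = [(r0, c0), (r0, c0 + scale),
                      (r0 + scale, c0 + scale), (r0 + scale, c0)]
    floor = 1e-8 * density.max()
    if density.max() == 0:
        density[:] = 1.0
    else:
        density += floor
    return DensityGrid(resolution=resolution, density=density,
                       node_corners=corners, scale=scale)


def density_equalize(
    grid: DensityGrid,
    tol: float = 1e-4,
    max_steps: int = 20000,
    dt0: float = 1e-3,
    pos_err: float = 1e-2,
    t_start: float = 0.05,
) -> EqualizedCoordinates:
    """Advect node-square corners through the diffusing density field.

    The diffusing field is a cosine series whose modes decay as
    exp(-|k|^2 t); points follow v = -grad(rho)/rho under an adaptive
    midpoint (predictor-corrector) scheme: a step is accepted only when
    the Euler and midpoint estimates agree within ``pos_err`` cells, the
    step size halving on rejection and growing after comfortable steps.

    rho and its gradient are evaluated from the cosine series exactly at
    the tracer positions (grid interpolation is too diffusive near the
    domain boundary and while features are still sub-cell); modes that
    have decayed to numerical irrelevance are dropped, so late steps are
    cheap.  Integration starts at a small positive time ``t_start``
    (damping the highest, ringing-prone modes) and stops once the
    per-step displacement falls below ``tol`` after the slowest mode has
    decayed substantially.

    Returns the displaced corners and each node's new position, the
    centroid of its displaced square.
    """
    n = grid.resolution
    rho0 = grid.density / grid.density.mean()
    rhat = dctn(rho0, type=2, norm="ortho")
    k = np.pi * np.arange(n) / n

    # adjacent squares share corners: advect each distinct corner once
    all_corners = grid.node_corners.reshape(-1, 2)
    pts, inverse = np.unique(all_corners, axis=0, return_inverse=True)
    pts = pts.astype(float)
    centers0 = grid.node_corners.mean(axis=1)

    # uniform density: no non-constant modes -> identity transform
    off_dc = rhat.copy()
    off_dc[0, 0] = 0.0
    if np.abs(off_dc).max() < 1e-12:
        return EqualizedCoordinates(coords=centers0.copy(),
                                    corners=grid.node_corners.copy(),
                                    original_coords=centers0)

    lam1 = (np.pi / n) ** 2            # slowest non-constant mode
    t_min = np.log(1e3) / lam1         # amplitudes down 1000x before tol applies
    t_end = np.log(1e8) / lam1         # hard stop: amplitudes down 1e8x

    # Where the rasterized density is (near) zero, -grad(rho)/rho is close
    # to singular; clamp the denominator to keep velocities bounded.
    rho_min = 1e-3

    # normalization constants of the orthonormal DCT-II basis
    cj = np.full(n, np.sqrt(2.0 / n))
    cj[0] = np.sqrt(1.0 / n)
    B0 = rhat * np.outer(cj, cj)

    def velocity(points: np.ndarray, t: float) -> np.ndarray:
        # exact series evaluation at the points: basis cos(k * p) with the
        # grid's cell centers at p = i + 0.5; decayed modes dropped
        decay1d = np.exp(-(k ** 2) * t)
        J = int(np.searchsorted(-decay1d, -1e-16))  # modes still alive
        J = max(J, 2)
        B = B0[:J, :J] * np.outer(decay1d[:J], decay1d[:J])
        kJ = k[:J]
        ar = np.outer(points[:, 0], kJ)
        ac = np.outer(points[:, 1], kJ)
        Cr, Sr = np.cos(ar), np.sin(ar)
        Cc, Sc = np.cos(ac), np.sin(ac)
        M = Cr @ B
        rho = (M * Cc).sum(axis=1)
        dc = -(M * Sc * kJ[None, :]).sum(axis=1)
        dr = -((Sr @ (B * kJ[:, None])) * Cc).sum(axis=1)
        r = np.maximum(rho, rho_min)
        return np.column_stack([-dr / r, -dc / r])

    t = float(t_start)
    dt = dt0
    steps = 0
    maxdisp = np.inf
    while t < t_end and steps < max_steps:
        steps += 1
        v1 = velocity(pts, t)
        mid = pts + v1 * (dt / 2.0)
        v2 = velocity(mid, t + dt / 2.0)
        err = np.abs((v2 - v1) * dt).max()  # Euler vs midpoint discrepancy
        if err > pos_err:
            dt /= 2.0
            continue
        disp = v2 * dt
        pts += disp
        t += dt
        maxdisp = np.abs(disp).max()
        if maxdisp < tol and t >= t_min:
            break
        if err < pos_err / 4.0:
            dt *= 1.5
    else:
        if t < t_end:
            raise RuntimeError(
                f"density equalization did not converge in {max_steps} steps "
                f"(t={t:.3g}, last step {maxdisp:.3g} cells)"
            )

    corners = pts[inverse].reshape(grid.node_corners.shape)
    coords = corners.mean(axis=1)
    return EqualizedCoordinates(coords=coords, corners=corners,
                                original_coords=centers0)


def square_areas(corners: np.ndarray) -> np.ndarray:
    """Shoelace area of each (possibly deformed) node square."""
    x = corners[..., 0]
    y = corners[..., 1]
    x2 = np.roll(x, -1, axis=-1)
    y2 = np.roll(y, -1, axis=-1)
    return 0.5 * np.abs((x * y2 - x2 * y).sum(axis=-1))
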