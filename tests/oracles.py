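"""Independent numerical oracles used only by the tests.

The diffusion oracle integrates the dimensionless 1-D diffusion equation
u_t = u_xx on a slab x in [0, 1] whose two faces are instantly equilibrated
(u(0, t) = u(1, t) = 0, initial condition u = 1) with a Crank-Nicolson
scheme, and reports the mean remaining moisture MR(Fo) = integral of u.
This is the geometry whose odd-mode eigen-decay is exp(-(2i-1)^2 pi^2 Fo)
with Fo = D t / L^2, L being the face-to-face thickness.  The oracle shares
no code with the analytical series implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded


def _banded(nx: int, r: float) -> np.ndarray:
    """(I - r L) in solve_banded layout, Dirichlet rows at both ends."""
    ab = np.zeros((3, nx))
    ab[0, 1:] = -r
    ab[1, :] = 1.0 + 2.0 * r
    ab[2, :-1] = -r
    for end in (0, nx - 1):
        ab[1, end] = 1.0
    ab[0, 1] = 0.0       # row 0 couples to nothing
    ab[2, nx - 2] = 0.0  # last row couples to nothing
    return ab


def _rhs(u: np.ndarray, r: float) -> np.ndarray:
    out = u.copy()
    out[1:-1] += r * (u[:-2] - 2.0 * u[1:-1] + u[2:])
    out[0] = 0.0
    out[-1] = 0.0
    return out


def finite_difference_slab_mr(fourier_numbers, nx: int = 401, dt: float = 1e-4):
    """MR at the requested Fourier numbers from a Crank-Nicolson PDE solve."""
    fo = np.asarray(fourier_numbers, dtype=float)
    if np.any(fo < 0):
        raise ValueError("negative Fourier number")
    order = np.argsort(fo)
    targets = fo[order]

    dx = 1.0 / (nx - 1)
    u = np.ones(nx)
    u[0] = u[-1] = 0.0
    r = dt / (2.0 * dx * dx)
    ab = _banded(nx, r)

    results = np.empty_like(targets)
    t = 0.0
    for i, target in enumerate(targets):
        while t + dt <= target + 1e-15:
            u = solve_banded((1, 1), ab, _rhs(u, r))
            t += dt
        if target > t:  # one shorter step to land exactly on the target
            r_last = (target - t) / (2.0 * dx * dx)
            u = solve_banded((1, 1), _banded(nx, r_last), _rhs(u, r_last))
            t = target
        results[i] = float(np.trapezoid(u, dx=dx))
    unsorted = np.empty_like(results)
    unsorted[order] = results
    return unsorted
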