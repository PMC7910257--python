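"""Independent oracles used by the test suite.

Everything here is implemented without calling the package's own solvers:
matrix-exponential propagation for the kinetic ODE (gamma inputs with
integer shape enter exactly through an Erlang chain augmentation),
quaternion (Cayley-Klein) spin-domain propagation for the Bloch
simulator, and a polynomial-evaluation form of the FIR envelope response.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def expm_timecourses(
    A: np.ndarray,
    times: np.ndarray,
    m0: np.ndarray,
    sub_index: int | None = None,
    alpha: int = 1,
    beta: float = 1.0,
    amplitude: float = 0.0,
) -> np.ndarray:
    """Analytic solution of dM/dt = A M + u(t) e_sub via augmentation.

    A gamma-variate input with integer shape ``alpha`` is the output of an
    Erlang chain of ``alpha`` first-order stages, so the driven system is
    equivalent to a larger homogeneous linear system solved exactly with
    the matrix exponential.  Returns magnetization (n_pools, len(times)).
    """
    n = A.shape[0]
    if amplitude == 0.0 or sub_index is None:
        out = np.empty((n, len(times)))
        for k, t in enumerate(times):
            out[:, k] = expm(A * t) @ m0
        return out
    a = int(alpha)
    if a != alpha or a < 1:
        raise ValueError("oracle supports integer alpha >= 1 only")
    aug = np.zeros((n + a, n + a))
    aug[:n, :n] = A
    aug[sub_index, n + a - 1] = 1.0 / beta
    aug[n, n] = -1.0 / beta
    for m in range(1, a):
        aug[n + m, n + m] = -1.0 / beta
        aug[n + m, n + m - 1] = 1.0 / beta
    x0 = np.concatenate([m0, np.zeros(a)])
    x0[n] = amplitude
    out = np.empty((n, len(times)))
    for k, t in enumerate(times):
        out[:, k] = (expm(aug * t) @ x0)[:n]
    return out


def _quat_mul(q1, q2):
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quaternion_bloch(rf, grad, raster, freq_hz, z_cm, gamma=1070.84):
    """Spin-domain propagation of a single isochromat from M = +z.

    Accumulates the net rotation as a unit quaternion (one rotation per
    raster sample, angle -2*pi*dt*|b| about b), then applies the
    equivalent rotation matrix to (0, 0, 1).  Returns (mxy, mz).
    """
    q = np.array([1.0, 0.0, 0.0, 0.0])
    dt = raster
    for k in range(len(rf)):
        bx = gamma * np.real(rf[k])
        by = gamma * np.imag(rf[k])
        bz = freq_hz + gamma * grad[k] * z_cm
        bn = np.sqrt(bx * bx + by * by + bz * bz)
        if bn == 0.0:
            continue
        theta = -2.0 * np.pi * dt * bn
        s = np.sin(theta / 2.0) / bn
        step = np.array([np.cos(theta / 2.0), bx * s, by * s, bz * s])
        q = _quat_mul(step, q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    m = rot @ np.array([0.0, 0.0, 1.0])
    return complex(m[0], m[1]), float(m[2])


def polyval_envelope(taps, freqs_hz, period_s):
    """FIR response as a polynomial in z = exp(-i 2 pi f T)."""
    taps = np.asarray(taps, dtype=float)
    f = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    z = np.exp(-2j * np.pi * f * period_s)
    # sum_k h_k z^k with polyval's descending-order convention
    return np.polyval(taps[::-1], z)


def measure_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a single-peaked curve by linear interpolation."""
    y = np.asarray(y, dtype=float)
    half = 0.5 * y.max()
    above = y >= half
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    if i0 == 0 or i1 == len(x) - 1:
        raise ValueError("peak not fully contained in the probed range")
    xl = x[i0 - 1] + (half - y[i0 - 1]) / (y[i0] - y[i0 - 1]) * (x[i0] - x[i0 - 1])
    xr = x[i1] + (half - y[i1]) / (y[i1 + 1] - y[i1]) * (x[i1 + 1] - x[i1])
    return float(xr - xl)
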