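"""Batched axis-angle propagation of classical magnetization vectors.

All public simulation entry points reduce to these two primitives: stepwise
propagation of a batch of unit vectors under a piecewise-constant field, and
composition of per-slice rotations into a net rotation matrix.  Field
components are given in Hz; each slice rotates the magnetization by
``2*pi*|w|*dt`` about ``w`` (exact Rodrigues rotation, no small-angle
approximation).
"""

from __future__ import annotations

import numpy as np


def _step(M: np.ndarray, wx, wy, wz, dt: float) -> np.ndarray:
    """Rotate batch ``M`` (B, 3) about the field (wx, wy, wz) [Hz] for dt [s]."""
    wn = np.sqrt(wx * wx + wy * wy + wz * wz)
    ang = 2.0 * np.pi * wn * dt
    safe = np.where(wn > 0.0, wn, 1.0)
    nx, ny, nz = wx / safe, wy / safe, wz / safe
    c = np.cos(ang)
    s = np.sin(ang)
    mx, my, mz = M[:, 0], M[:, 1], M[:, 2]
    ndot = nx * mx + ny * my + nz * mz
    cx = ny * mz - nz * my
    cy = nz * mx - nx * mz
    cz = nx * my - ny * mx
    k = 1.0 - c
    return np.stack(
        [
            mx * c + cx * s + nx * ndot * k,
            my * c + cy * s + ny * ndot * k,
            mz * c + cz * s + nz * ndot * k,
        ],
        axis=1,
    )


def propagate_fields(
    wx: np.ndarray,
    wy: np.ndarray,
    wz: np.ndarray,
    dt: float,
    m0: np.ndarray,
    record_stride: int | None = None,
) -> np.ndarray:
    """Propagate under a (T, B) field table.

    Parameters
    ----------
    wx, wy, wz:
        Field components in Hz, shape (T, B) (or broadcastable to it).
    dt:
        Slice duration in seconds.
    m0:
        Initial magnetization, shape (B, 3) or (3,).
    record_stride:
        If given, additionally record the state every ``record_stride``
        slices (including the initial state) and return the trajectory of
        shape (T // record_stride + 1, B, 3).  Otherwise return the final
        state (B, 3).
    """
    wx, wy, wz = np.broadcast_arrays(np.asarray(wx, float), np.asarray(wy, float), np.asarray(wz, float))
    if wx.ndim != 2:
        raise ValueError("field tables must be 2-D (time, batch)")
    if not (np.all(np.isfinite(wx)) and np.all(np.isfinite(wy)) and np.all(np.isfinite(wz))):
        raise ValueError("non-finite field value in waveform")
    T, B = wx.shape
    M = np.array(np.broadcast_to(np.asarray(m0, float), (B, 3)), dtype=float)
    if record_stride is None:
        for t in range(T):
            M = _step(M, wx[t], wy[t], wz[t], dt)
        return M
    traj = np.empty((T // record_stride + 1, B, 3))
    traj[0] = M
    for t in range(T):
        M = _step(M, wx[t], wy[t], wz[t], dt)
        if (t + 1) % record_stride == 0:
            traj[(t + 1) // record_stride] = M
    return traj


def compose_rotations(wx: np.ndarray, wy: np.ndarray, wz: np.ndarray, dt: float) -> np.ndarray:
    """Compose per-slice rotations into net rotation matrices, shape (B, 3, 3).

    The returned matrix maps an initial magnetization vector to the final one:
    ``M_final = R @ M_initial``, identical (to rounding) to `propagate_fields`
    applied to the same field table.
    """
    wx, wy, wz = np.broadcast_arrays(np.asarray(wx, float), np.asarray(wy, float), np.asarray(wz, float))
    T, B = wx.shape
    R = np.broadcast_to(np.eye(3), (B, 3, 3)).copy()
    Rt = np.empty((B, 3, 3))
    for t in range(T):
        ax, ay, az = wx[t], wy[t], wz[t]
        wn = np.sqrt(ax * ax + ay * ay + az * az)
        ang = 2.0 * np.pi * wn * dt
        safe = np.where(wn > 0.0, wn, 1.0)
        nx, ny, nz = ax / safe, ay / safe, az / safe
        c = np.cos(ang)
        s = np.sin(ang)
        k = 1.0 - c
        Rt[:, 0, 0] = c + nx * nx * k
        Rt[:, 0, 1] = nx * ny * k - nz * s
        Rt[:, 0, 2] = nx * nz * k + ny * s
        Rt[:, 1, 0] = ny * nx * k + nz * s
        Rt[:, 1, 1] = c + ny * ny * k
        Rt[:, 1, 2] = ny * nz * k - nx * s
        Rt[:, 2, 0] = nz * nx * k - ny * s
        Rt[:, 2, 1] = nz * ny * k + nx * s
        Rt[:, 2, 2] = c + nz * nz * k
        R = Rt @ R
    return R


def rotation_vector(R: np.ndarray) -> np.ndarray:
    """Axis-angle (rotation vector) of a batch of rotation matrices (B, 3, 3)."""
    R = np.asarray(R, float)
    tr = np.clip((R[..., 0, 0] + R[..., 1, 1] + R[..., 2, 2] - 1.0) / 2.0, -1.0, 1.0)
    ang = np.arccos(tr)
    ax = np.stack(
        [
            R[..., 2, 1] - R[..., 1, 2],
            R[..., 0, 2] - R[..., 2, 0],
            R[..., 1, 0] - R[..., 0, 1],
        ],
        axis=-1,
    )
    sin_ang = np.sin(ang)
    scale = np.where(sin_ang > 1e-12, ang / np.where(sin_ang > 1e-12, 2.0 * sin_ang, 1.0), 0.5)
    return ax * scale[..., None]
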