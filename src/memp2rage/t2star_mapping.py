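"""Mono-exponential T2* estimation by log-linear least squares.

ln(S) is regressed on echo time; the slope gives -1/T2* and the intercept
ln(S0).  The fit is unweighted ordinary least squares, solved through a
rank-revealing decomposition (numpy's SVD-based ``lstsq``).  Voxels with
any non-positive magnitude, fewer than two echoes, or a non-negative
slope (no decay) are masked out rather than raising; the masked T2* is
reported as the +inf sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import VolumeMap

__all__ = ["DecaySeries", "fit_loglinear", "fit_volume", "fit_loglinear_stack"]


@dataclass(frozen=True)
class DecaySeries:
    """Echo times (s) and per-echo magnitudes for one voxel."""

    te: np.ndarray
    mag: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        mag = np.asarray(self.mag, dtype=float)
        if te.shape != mag.shape or te.ndim != 1:
            raise ValueError("te and mag must be congruent 1-D arrays")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "mag", mag)


def fit_loglinear_stack(te, mags, weighted: bool = False):
    """Vectorized log-linear fit of echo-stacked magnitudes.

    ``mags`` has the echo axis first, any voxel shape after.  Returns
    ``(s0, t2star, valid)``; invalid voxels carry s0 = 0, t2star = +inf.
    With ``weighted=True`` each echo is weighted by its magnitude
    (first-order noise propagation of the log transform); the default is
    the plain unweighted fit.
    """
    te = np.asarray(te, dtype=float)
    mags = np.asarray(mags, dtype=float)
    if mags.shape[0] != te.size:
        raise ValueError("echo axis of mags must match te")
    shape = mags.shape[1:]
    flat = mags.reshape(te.size, -1)
    valid = np.all(flat > 0, axis=0) & np.all(np.isfinite(flat), axis=0)
    if te.size < 2:
        valid[:] = False

    s0 = np.zeros(flat.shape[1])
    t2s = np.full(flat.shape[1], np.inf)
    if np.any(valid):
        y = np.log(flat[:, valid])
        x = np.column_stack([np.ones_like(te), te])
        if weighted:
            # solve per-voxel weighted normal equations; weights ~ magnitude
            w = flat[:, valid]
            sw = (w**2).sum(0)
            swt = (w**2 * te[:, None]).sum(0)
            swt2 = (w**2 * te[:, None] ** 2).sum(0)
            swy = (w**2 * y).sum(0)
            swty = (w**2 * te[:, None] * y).sum(0)
            det = sw * swt2 - swt**2
            inter = (swt2 * swy - swt * swty) / det
            slope = (sw * swty - swt * swy) / det
        else:
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            inter, slope = coef
        s0_v = np.exp(inter)
        with np.errstate(divide="ignore"):
            t2_v = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), np.inf)
        ok = slope < 0
        idx = np.flatnonzero(valid)
        s0[idx] = np.where(ok, s0_v, 0.0)
        t2s[idx] = t2_v
        valid[idx] = ok
    return s0.reshape(shape), t2s.reshape(shape), valid.reshape(shape)


def fit_loglinear(series: DecaySeries, weighted: bool = False):
    """Fit one decay series; returns ``(s0, t2star, valid)``.

    ``t2star`` is +inf and ``valid`` False for degenerate input (any
    non-positive magnitude, <2 echoes, or non-decaying signal).
    """
    s0, t2s, valid = fit_loglinear_stack(series.te, series.mag[:, None], weighted=weighted)
    return float(s0[0]), float(t2s[0]), bool(valid[0])


def fit_volume(echo_volumes, te, weighted: bool = False):
    """Voxelwise log-linear T2* fit of a list of congruent echo volumes.

    Accepts a list of :class:`VolumeMap` (or arrays) of identical shape.
    Returns ``(t2star_map, s0_map)`` as VolumeMaps (seconds / a.u.) whose
    mask combines input masks with fit validity.
    """
    te = np.asarray(te, dtype=float)
    if len(echo_volumes) != te.size:
        raise ValueError("number of echo volumes must match te")
    is_vol = isinstance(echo_volumes[0], VolumeMap)
    arrays, mask = [], None
    for v in echo_volumes:
        a = v.data if isinstance(v, VolumeMap) else np.asarray(v)
        arrays.append(np.abs(a) if np.iscomplexobj(a) else a)
        if isinstance(v, VolumeMap) and v.mask is not None:
            mask = v.mask if mask is None else (mask & v.mask)
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("echo volumes are not congruent")
    stack = np.stack(arrays, axis=0)
    s0, t2s, valid = fit_loglinear_stack(te, stack, weighted=weighted)
    if mask is not None:
        valid &= mask
    vox = echo_volumes[0].voxel_size if is_vol else (1.0, 1.0, 1.0)
    t2_map = VolumeMap(t2s, voxel_size=vox, units="s", mask=valid,
                       provenance=["fit_volume:loglinear"])
    s0_map = VolumeMap(s0, voxel_size=vox, units="a.u.", mask=valid,
                       provenance=["fit_volume:loglinear"])
    return t2_map, s0_map
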