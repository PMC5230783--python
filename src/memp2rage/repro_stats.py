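"""Voxel-by-voxel agreement statistics and robustness sweeps.

The core comparison of a test map x against a reference map y over a
mask of N voxels uses the difference D_i = y_i - x_i:

    mu_D   = mean(D)                      accuracy
    sigma_D = sqrt(mean((D - mu_D)^2))    precision
    mu_|D| = mean(|D|)                    overall reproducibility
    sigma_|D| = sqrt(mean((|D| - mu_D)^2))

together with the squared Pearson correlation r^2 of (x, y).  The
sigma_|D| definition above centers |D| on mu_D; the conventional spread
of |D| (centered on mu_|D|) is also computed, and the first form is the
default report (see the methods note for the rationale).

Robustness sweeps re-run this comparison after known rigid transforms
(axial rotation about the FOV center followed by axial translation) or
after re-running the susceptibility chain on noise-degraded complex
data, mirroring test-retest mis-registration and SNR analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .qsm import KGrid, compute_chi
from .volumes import VolumeMap, wrap_phase

__all__ = ["DiffStats", "RigidTransform", "diff_stats", "hist2d", "apply_rigid",
           "misregistration_sweep", "noise_sweep", "roi_stats"]


@dataclass(frozen=True)
class DiffStats:
    """Agreement statistics for one map pair, in the maps' units."""

    mu_d: float
    sigma_d: float
    mu_abs_d: float
    sigma_abs_d: float            # |D| centered on mu_D (default report)
    sigma_abs_d_conventional: float  # |D| centered on mu_|D|
    r2: float                     # NaN (with flag) if either map is constant
    n_voxels: int
    r2_defined: bool = True

    def as_dict(self) -> dict:
        return {"mu_D": self.mu_d, "sigma_D": self.sigma_d,
                "mu_absD": self.mu_abs_d, "sigma_absD": self.sigma_abs_d,
                "sigma_absD_conventional": self.sigma_abs_d_conventional,
                "r2": self.r2, "n_voxels": self.n_voxels}


@dataclass(frozen=True)
class RigidTransform:
    """Axial rotation (degrees, about the FOV center) then axial translation (voxels)."""

    rotation_deg: float = 0.0
    translation_px: float = 0.0


def _masked_pair(test, ref, mask):
    x = np.asarray(test.data if isinstance(test, VolumeMap) else test, dtype=float)
    y = np.asarray(ref.data if isinstance(ref, VolumeMap) else ref, dtype=float)
    if x.shape != y.shape:
        raise ValueError("test and reference maps are not congruent")
    if mask is None:
        m = np.isfinite(x) & np.isfinite(y)
    else:
        m = np.asarray(mask, dtype=bool) & np.isfinite(x) & np.isfinite(y)
    if not m.any():
        raise ValueError("mask is empty")
    return x[m], y[m]


def diff_stats(test, ref, mask=None) -> DiffStats:
    """Agreement statistics of a test map against a reference map.

    D = reference - test.  Voxels where either map is non-finite are
    excluded.  If either map has zero variance r^2 is undefined and
    reported as NaN with ``r2_defined=False``.
    """
    x, y = _masked_pair(test, ref, mask)
    d = y - x
    mu_d = d.mean()
    sigma_d = float(np.sqrt(np.mean((d - mu_d) ** 2)))
    abs_d = np.abs(d)
    mu_abs = float(abs_d.mean())
    sigma_abs = float(np.sqrt(np.mean((abs_d - mu_d) ** 2)))
    sigma_abs_conv = float(np.sqrt(np.mean((abs_d - mu_abs) ** 2)))
    defined = x.std() > 0 and y.std() > 0
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2) if defined else float("nan")
    return DiffStats(mu_d=float(mu_d), sigma_d=sigma_d, mu_abs_d=mu_abs,
                     sigma_abs_d=sigma_abs, sigma_abs_d_conventional=sigma_abs_conv,
                     r2=r2, n_voxels=int(x.size), r2_defined=defined)


def hist2d(test, ref, mask=None, bins: int = 128, value_range=None):
    """Joint (2-D correlation) histogram of a map pair.

    ``value_range`` defaults to the central 99% of each map's values.
    Returns ``(counts, x_edges, y_edges)``; the total count equals the
    number of masked voxels falling inside the range.
    """
    x, y = _masked_pair(test, ref, mask)
    if value_range is None:
        value_range = (tuple(np.percentile(x, [0.5, 99.5])),
                       tuple(np.percentile(y, [0.5, 99.5])))
    (x_lo, x_hi), (y_lo, y_hi) = value_range
    if not (x_hi > x_lo and y_hi > y_lo):
        raise ValueError("histogram range is empty")
    counts, xe, ye = np.histogram2d(x, y, bins=bins,
                                    range=[[x_lo, x_hi], [y_lo, y_hi]])
    return counts, xe, ye


def apply_rigid(vol, t: RigidTransform, interp: str = "trilinear"):
    """Resample a volume under a known rigid transform.

    Rotation is about the third (axial) axis, centered at the geometric
    center of the FOV; translation is along that same axis.  Samples
    falling outside the volume are NaN and excluded from the returned
    validity mask.  Returns ``(resampled, valid_mask)`` (the resampled
    object mirrors the input type).
    """
    is_vol = isinstance(vol, VolumeMap)
    data = np.asarray(vol.data if is_vol else vol, dtype=float)
    order = {"trilinear": 1, "nearest": 0}[interp]
    theta = np.deg2rad(t.rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    # output voxel -> input voxel mapping (inverse transform), rotating in
    # the plane perpendicular to the axial axis
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    center = (np.asarray(data.shape) - 1) / 2.0
    offset = center - rot @ center
    offset[2] -= t.translation_px
    out = ndimage.affine_transform(data, rot, offset=offset, order=order,
                                   mode="constant", cval=np.nan, prefilter=False)
    valid = np.isfinite(out)
    if is_vol:
        res = vol.with_data(out, step=f"apply_rigid(rot={t.rotation_deg}deg,dz={t.translation_px}px)")
        res.mask = valid if vol.mask is None else (valid & vol.mask)
        return res, valid
    return out, valid


def misregistration_sweep(vol, offsets_px: Iterable[float],
                          angles_deg: Iterable[float], mask=None,
                          interp: str = "trilinear") -> pd.DataFrame:
    """Compare a map against rigidly transformed copies of itself.

    One row per (rotation, translation) pair on the grid of the two
    sweeps, containing the transform parameters and the difference
    statistics of original vs transformed map.
    """
    rows = []
    for ang in angles_deg:
        for off in offsets_px:
            t = RigidTransform(rotation_deg=ang, translation_px=off)
            moved, valid = apply_rigid(vol, t, interp=interp)
            m = valid if mask is None else (valid & np.asarray(mask, dtype=bool))
            moved_data = moved.data if isinstance(moved, VolumeMap) else moved
            st = diff_stats(vol, moved_data, m)
            rows.append({"rotation_deg": ang, "translation_px": off, **st.as_dict()})
    return pd.DataFrame(rows)


def noise_sweep(acq, noise_sds: Iterable[float], echo_index: int = -1,
                seed: int = 0, **chain_kwargs) -> pd.DataFrame:
    """Susceptibility-map degradation under added complex noise.

    The baseline chi map is computed from the acquisition's second
    inversion volume at ``echo_index``; for each noise SD, independent
    Gaussian noise is added to the real and imaginary parts of that
    complex volume, the full susceptibility chain is re-run, and the
    result is compared to the baseline over the (eroded) mask.
    """
    from dataclasses import replace as _dc_replace

    from .acquisition import echo_times

    fc = _dc_replace(acq.field_constants,
                     te_qsm=echo_times(acq.protocol)[echo_index])
    base_cplx = acq.inv2[echo_index]
    kg = KGrid(base_cplx.shape, acq.truth.spec.voxel_size)
    base_chi, eroded = compute_chi(np.angle(base_cplx), acq.mask, fc, kg, **chain_kwargs)
    rng = np.random.default_rng(seed)
    rows = []
    for sd in noise_sds:
        noisy = base_cplx + sd * (rng.standard_normal(base_cplx.shape)
                                  + 1j * rng.standard_normal(base_cplx.shape))
        chi, er = compute_chi(np.angle(noisy), acq.mask, fc, kg, **chain_kwargs)
        st = diff_stats(base_chi, chi, er & eroded)
        rows.append({"noise_sd": sd, **st.as_dict()})
    return pd.DataFrame(rows)


def roi_stats(vol, labels, label_names: Optional[dict] = None) -> pd.DataFrame:
    """Per-label mean and SD of a map.

    ``labels`` is an integer label volume; label 0 is background and is
    skipped.  Requested names absent from the volume are omitted.
    """
    data = np.asarray(vol.data if isinstance(vol, VolumeMap) else vol, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != data.shape:
        raise ValueError("labels are not congruent with the map")
    rows = []
    for code in np.unique(labels):
        if code == 0:
            continue
        sel = (labels == code) & np.isfinite(data)
        if not sel.any():
            continue
        name = (label_names or {}).get(int(code), str(int(code)))
        rows.append({"label": int(code), "name": name,
                     "mean": float(data[sel].mean()),
                     "sd": float(data[sel].std(ddof=0)),
                     "n_voxels": int(sel.sum())})
    return pd.DataFrame(rows)
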