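"""Synthetic 3-D brain phantom and forward acquisition simulator.

The phantom is a nested-ellipsoid digital brain: a cortical gray-matter
shell around a white-matter interior, a CSF core standing in for the
ventricles, and embedded deep-gray nuclei (putamen, caudate, thalamus).
Per-class T1, T2* and susceptibility defaults are the in-vivo 7 T group
values of the region-of-interest analysis this package models; CSF T1 is
not part of that table and defaults to 4.3 s (a literature-typical 7 T
value) so that lookup-clamping behavior can be exercised.

The forward simulator composes the closed-form block signal model with
the spectral dipole field: per voxel and echo the magnitude follows the
two-inversion signal equations (with an optional smooth B1+ scale field
applied to the flip angles), the phase is the wrapped dipole-field phase
at that echo time, and independent complex Gaussian noise is added.  All
randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acquisition import ProtocolParams, echo_times
from .qsm import FieldConstants, KGrid, forward_field
from .signal_model import block_center_signals
from .volumes import wrap_phase

__all__ = ["TISSUE_CLASSES", "DEFAULT_TISSUES", "PhantomSpec", "PhantomTruth",
           "SyntheticAcquisition", "make_phantom", "simulate_acquisition"]

# label codes
TISSUE_CLASSES = {
    "background": 0,
    "wm": 1,
    "gm": 2,
    "csf": 3,
    "putamen": 4,
    "caudate": 5,
    "thalamus": 6,
}

# per-class (m0 [a.u.], t1 [s], t2star [s], chi [ppb]); T1/T2*/chi from the
# 7 T ROI group means (GM uses the frontal-lobe column), chi referenced to
# the cortical average.  CSF values are synthetic stand-ins (see module
# docstring); M0 is a plausible relative proton density.
DEFAULT_TISSUES = {
    "wm": (0.70, 1.219, 0.02585, 7.0),
    "gm": (0.85, 1.802, 0.0331, -0.3),
    "csf": (1.00, 4.3, 0.050, 0.0),
    "putamen": (0.82, 1.659, 0.0332, -0.4),
    "caudate": (0.82, 1.441, 0.0274, 26.3),
    "thalamus": (0.82, 1.696, 0.0307, -1.5),
}

# per-class SDs of the same table, for optional jitter: (t1, t2star, chi)
TISSUE_SDS = {
    "wm": (0.030, 0.0008, 2.3),
    "gm": (0.051, 0.0017, 1.0),
    "csf": (0.0, 0.0, 0.0),
    "putamen": (0.036, 0.0019, 1.4),
    "caudate": (0.034, 0.0011, 3.4),
    "thalamus": (0.044, 0.0019, 1.6),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue table and randomness of the synthetic brain."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 0.6)
    tissue_table: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    jitter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 8 for n in self.shape):
            raise ValueError("phantom shape must be 3-D with at least 8 voxels per axis")
        missing = set(DEFAULT_TISSUES) - set(self.tissue_table)
        if missing:
            raise ValueError(f"tissue_table missing classes: {sorted(missing)}")


@dataclass
class PhantomTruth:
    """Ground-truth maps: labels plus per-voxel M0/T1/T2*/chi."""

    labels: np.ndarray
    m0: np.ndarray
    t1: np.ndarray
    t2star: np.ndarray
    chi: np.ndarray
    mask: np.ndarray
    spec: PhantomSpec


@dataclass
class SyntheticAcquisition:
    """Complex echo volumes per inversion block plus the generating truth."""

    inv1: np.ndarray  # (n_echoes, *shape) complex
    inv2: np.ndarray
    truth: PhantomTruth
    protocol: ProtocolParams
    field_constants: FieldConstants
    field_ppb: np.ndarray
    noise_sd: float
    seed: int

    @property
    def mask(self) -> np.ndarray:
        return self.truth.mask


def _ellipsoid(shape, center, semi):
    """Boolean ellipsoid; center and semi-axes in fractions of the FOV."""
    grids = np.meshgrid(*[np.linspace(-0.5, 0.5, n) for n in shape],
                        indexing="ij", sparse=True)
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomTruth:
    """Build the nested-ellipsoid label volume and its truth maps.

    Deterministic given ``spec.seed``; with ``jitter=True`` each class
    value is perturbed voxelwise by the published per-class SDs.
    """
    sh = spec.shape
    labels = np.zeros(sh, dtype=np.int8)
    brain = _ellipsoid(sh, (0, 0, 0), (0.44, 0.40, 0.37))
    inner = _ellipsoid(sh, (0, 0, 0), (0.36, 0.32, 0.29))
    labels[brain] = TISSUE_CLASSES["gm"]
    labels[inner] = TISSUE_CLASSES["wm"]
    # ventricle-like CSF core
    labels[_ellipsoid(sh, (0.0, -0.04, 0.0), (0.10, 0.13, 0.07))] = TISSUE_CLASSES["csf"]
    # bilateral nuclei
    for side in (-1, 1):
        labels[_ellipsoid(sh, (side * 0.17, 0.02, -0.02), (0.06, 0.05, 0.07))] = TISSUE_CLASSES["putamen"]
        labels[_ellipsoid(sh, (side * 0.09, 0.14, 0.04), (0.045, 0.06, 0.05))] = TISSUE_CLASSES["caudate"]
        labels[_ellipsoid(sh, (side * 0.08, -0.14, -0.03), (0.055, 0.07, 0.06))] = TISSUE_CLASSES["thalamus"]

    rng = np.random.default_rng(spec.seed)
    m0 = np.zeros(sh)
    t1 = np.full(sh, np.inf)
    t2s = np.full(sh, np.inf)
    chi = np.zeros(sh)
    for name, code in TISSUE_CLASSES.items():
        if name == "background":
            continue
        sel = labels == code
        m, v1, v2, vc = spec.tissue_table[name]
        if spec.jitter:
            s1, s2, sc = TISSUE_SDS[name]
            t1[sel] = np.maximum(v1 + s1 * rng.standard_normal(sel.sum()), 0.05)
            t2s[sel] = np.maximum(v2 + s2 * rng.standard_normal(sel.sum()), 0.001)
            chi[sel] = vc + sc * rng.standard_normal(sel.sum())
        else:
            t1[sel] = v1
            t2s[sel] = v2
            chi[sel] = vc
        m0[sel] = m
    return PhantomTruth(labels=labels, m0=m0, t1=t1, t2star=t2s, chi=chi,
                        mask=labels > 0, spec=spec)


def smooth_b1_field(shape, amplitude: float = 0.2) -> np.ndarray:
    """A smooth center-bright B1+ multiplier field, 1 at the FOV center."""
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape],
                        indexing="ij", sparse=True)
    r2 = sum(g**2 for g in grids)
    return 1.0 - amplitude * r2 / 3.0


def simulate_acquisition(truth: PhantomTruth, p: ProtocolParams,
                         noise_sd: float = 0.0,
                         fc: FieldConstants | None = None,
                         seed: int = 0,
                         b1_scale_field: Optional[np.ndarray] = None,
                         background_field_ppb: Optional[np.ndarray] = None,
                         scanner_scale: float = 1.0) -> SyntheticAcquisition:
    """Forward-simulate complex two-inversion multi-echo volumes.

    Magnitudes come from the closed-form block signals (T1, M0, optional
    per-voxel flip-angle scale); the phase at echo time TE is the wrapped
    dipole field of the chi map (plus an optional background field, both
    in ppb) scaled by 1e-9 * gamma * TE * B0.  Independent Gaussian noise
    of SD ``noise_sd`` is added to the real and imaginary parts of every
    echo volume.  Deterministic given ``seed``.
    """
    fc = fc or FieldConstants()
    kg = KGrid(truth.labels.shape, truth.spec.voxel_size)
    flip = 1.0 if b1_scale_field is None else np.asarray(b1_scale_field)

    # T1 = inf in background is unphysical for the recursion; signal is 0
    # there anyway because M0 = 0, so substitute a finite dummy value.
    t1 = np.where(np.isfinite(truth.t1), truth.t1, 1.0)
    u1, u2, _ = block_center_signals(p, t1, truth.m0, flip)

    field = forward_field(truth.chi, kg)
    if background_field_ppb is not None:
        field = field + np.asarray(background_field_ppb)

    te = np.asarray(echo_times(p))
    rng = np.random.default_rng(seed)
    shape = (te.size,) + truth.labels.shape
    inv1 = np.empty(shape, dtype=complex)
    inv2 = np.empty(shape, dtype=complex)
    with np.errstate(invalid="ignore"):
        decay = np.exp(-te[:, None, None, None] / truth.t2star)
    decay = np.nan_to_num(decay, nan=0.0) * scanner_scale
    for i, t in enumerate(te):
        phase = wrap_phase(1e-9 * fc.gamma * t * fc.b0 * field)
        carrier = np.exp(1j * phase)
        for arr, u in ((inv1, u1), (inv2, u2)):
            clean = decay[i] * u * carrier
            noise = noise_sd * (rng.standard_normal(clean.shape)
                                + 1j * rng.standard_normal(clean.shape))
            arr[i] = clean + noise
    return SyntheticAcquisition(inv1=inv1, inv2=inv2, truth=truth, protocol=p,
                                field_constants=fc, field_ppb=field,
                                noise_sd=noise_sd, seed=seed)
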