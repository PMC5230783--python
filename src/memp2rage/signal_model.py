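"""Closed-form (ME-)MP2RAGE signal model.

One sequence period consists of: adiabatic inversion, free relaxation over
T_A, a GRE block of ``n`` spoiled excitations with flip angle alpha_1 (one
line period ``tr_gre`` each), relaxation over T_B, a second block with
alpha_2, and relaxation over T_C back to the next inversion.  Every step
acts on the longitudinal magnetization as an affine map
``mz -> a*mz + b``; composing the period gives a contraction whose fixed
point is the steady-state magnetization Mz_ss (reported here at the
instant just before the inversion pulse).

The image signal of block ``j`` at echo time TE_i is

    S_j(TE_i) = xi * sin(alpha_j) * Mz(center_j) * exp(-TE_i / T2*)

with ``Mz(center_j)`` the longitudinal magnetization just before the
excitation of the k-space center line, obtained in closed form from the
geometric-series solution of the intra-block recursion.  ``xi`` lumps all
scanner gains.  Signals are real-valued; field-dependent phase is added by
the phantom simulator.

The two inversion contrasts are combined into the bias-cancelling uniform
image  rho = Re[S1* S2] / (|S1|^2 + |S2|^2),  bounded in [-1/2, 1/2] and
monotonic in T1 over a protocol-dependent range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import (
    ProtocolParams,
    SequenceKind,
    derive_gaps,
    echo_times,
    n_lines_before_center,
)

__all__ = [
    "TissueParams",
    "BlockSignals",
    "steady_state_mz",
    "block_signals",
    "block_center_signals",
    "rho_combine",
    "rho_of_t1",
    "flash_signals",
]


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth tissue parameters for a voxel or tissue class.

    ``m0`` is the equilibrium magnetization (arbitrary units), ``chi`` the
    bulk magnetic susceptibility in ppb (used only by the phantom and QSM
    stages), ``scanner_scale`` the lumped gain xi.
    """

    m0: float = 1.0
    t1: float = 1.0
    t2star: float = np.inf
    chi: float = 0.0
    scanner_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")
        if self.t1 <= 0 or self.t2star <= 0:
            raise ValueError("relaxation times must be positive")


@dataclass(frozen=True)
class BlockSignals:
    """Per-echo signals of the two GRE blocks plus the steady state."""

    s1: np.ndarray
    s2: np.ndarray
    mz_ss: float | np.ndarray

    def __post_init__(self) -> None:
        if np.shape(self.s1) != np.shape(self.s2):
            raise ValueError("s1 and s2 must be congruent")


def _compose(a1, b1, a2, b2):
    """Affine map (a2, b2) applied after (a1, b1)."""
    return a2 * a1, a2 * b1 + b2


def _relax(tau, t1, m0):
    e = np.exp(-tau / t1)
    return e, m0 * (1.0 - e)


def _block(k, cos_a, e1, m0):
    """k spoiled excitations + line-period relaxations, in closed form."""
    q = e1 * cos_a
    qk = q**k
    # geometric series; q == 1 only for alpha = 0 and T1 = inf
    b = m0 * (1.0 - e1) * np.where(q == 1.0, float(k), (1.0 - qk) / np.where(q == 1.0, 1.0, 1.0 - q))
    return qk, b


def _period_map(p: ProtocolParams, t1, m0, flip_scale=1.0):
    """Affine map of one full period, starting just before the inversion."""
    t_a, t_b, t_c = derive_gaps(p)
    a1 = np.deg2rad(p.effective_alpha_1) * flip_scale
    a2 = np.deg2rad(p.effective_alpha_2) * flip_scale
    e1 = np.exp(-p.tr_gre / np.asarray(t1, dtype=float))
    eta = p.inv_efficiency

    a, b = (1.0 - 2.0 * eta) * np.ones_like(e1), np.zeros_like(e1)
    for step in (
        _relax(t_a, t1, m0),
        _block(p.n_lines, np.cos(a1), e1, m0),
        _relax(t_b, t1, m0),
        _block(p.n_lines, np.cos(a2), e1, m0),
        _relax(t_c, t1, m0),
    ):
        a, b = _compose(a, b, *step)
    return a, b


def steady_state_mz(p: ProtocolParams, t: TissueParams) -> float:
    """Steady-state longitudinal magnetization just before the inversion.

    Fixed point ``b / (1 - a)`` of the one-period affine map.  Raises if
    the period map is not a contraction (impossible for physical inputs).
    """
    a, b = _period_map(p, t.t1, t.m0)
    if np.any(np.abs(a) >= 1.0):
        raise ValueError("period map is not contractive; check protocol/tissue values")
    return float(b / (1.0 - a))


def block_center_signals(p: ProtocolParams, t1, m0=1.0, flip_scale=1.0):
    """Signals at the k-space center of each block, before T2* decay.

    Vectorized over broadcastable arrays ``t1``, ``m0`` and ``flip_scale``
    (the latter modelling a per-voxel B1+ offset on both flip angles).
    Returns ``(u1, u2, mz_ss)`` where ``u_j = sin(alpha_j) * Mz(center_j)``.
    """
    t1 = np.asarray(t1, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    flip_scale = np.asarray(flip_scale, dtype=float)
    t1, m0, flip_scale = np.broadcast_arrays(t1, m0, flip_scale)

    a, b = _period_map(p, t1, m0, flip_scale)
    if np.any(np.abs(a) >= 1.0):
        raise ValueError("period map is not contractive")
    mz_ss = b / (1.0 - a)

    t_a, t_b, _ = derive_gaps(p)
    nb = n_lines_before_center(p)
    a1 = np.deg2rad(p.effective_alpha_1) * flip_scale
    a2 = np.deg2rad(p.effective_alpha_2) * flip_scale
    e1 = np.exp(-p.tr_gre / t1)
    eta = p.inv_efficiency

    # propagate from the steady state to the two center lines
    mz = (1.0 - 2.0 * eta) * mz_ss
    ar, br = _relax(t_a, t1, m0)
    mz = ar * mz + br
    ab, bb = _block(nb, np.cos(a1), e1, m0)
    mz_c1 = ab * mz + bb
    ab, bb = _block(p.n_lines - nb, np.cos(a1), e1, m0)
    mz = ab * mz_c1 + bb
    ar, br = _relax(t_b, t1, m0)
    mz = ar * mz + br
    ab, bb = _block(nb, np.cos(a2), e1, m0)
    mz_c2 = ab * mz + bb

    return np.sin(a1) * mz_c1, np.sin(a2) * mz_c2, mz_ss


def block_signals(p: ProtocolParams, t: TissueParams, flip_scale: float = 1.0) -> BlockSignals:
    """Per-echo signals of both blocks for a single tissue.

    Applies the common factor ``xi * exp(-TE_i / T2*)`` to the center-line
    magnetizations of :func:`block_center_signals`.
    """
    u1, u2, mz_ss = block_center_signals(p, t.t1, t.m0, flip_scale)
    te = np.asarray(echo_times(p))
    decay = t.scanner_scale * np.exp(-te / t.t2star)
    return BlockSignals(s1=decay * u1, s2=decay * u2, mz_ss=float(mz_ss))


def rho_combine(s1, s2, return_flag: bool = False):
    """Uniform-image combination  Re[s1* s2] / (|s1|^2 + |s2|^2).

    Result lies in [-1/2, 1/2].  Where both signals vanish the ratio is
    undefined; it is reported as 0 and, with ``return_flag=True``, marked
    in a companion boolean array.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    num = np.real(np.conj(s1) * s2)
    den = np.abs(s1) ** 2 + np.abs(s2) ** 2
    bad = den == 0
    rho = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    if rho.ndim == 0:
        rho = float(rho)
        bad = bool(bad)
    if return_flag:
        return rho, bad
    return rho


def rho_of_t1(p: ProtocolParams, t1, flip_scale=1.0):
    """rho as a function of T1 for a protocol (first echo; decay cancels)."""
    u1, u2, _ = block_center_signals(p, t1, 1.0, flip_scale)
    return rho_combine(u1, u2)


def flash_signals(p: ProtocolParams, t: TissueParams, flip_scale: float = 1.0) -> np.ndarray:
    """Spoiled-GRE (FLASH) steady-state signal per echo.

    S(TE_i) = xi * M0 * sin(a) * (1 - E1) / (1 - E1 cos a) * exp(-TE_i/T2*)
    with E1 = exp(-TR / T1) and TR the line repetition time.
    """
    if p.sequence_kind is not SequenceKind.ME_FLASH:
        raise ValueError("flash_signals expects an me_flash protocol")
    a = np.deg2rad(p.effective_alpha_1) * flip_scale
    e1 = np.exp(-p.tr_gre / t.t1)
    amp = t.scanner_scale * t.m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    te = np.asarray(echo_times(p))
    return amp * np.exp(-te / t.t2star)
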