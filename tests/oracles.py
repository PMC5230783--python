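"""Independent oracles used to cross-check the package implementation.

Everything here is deliberately naive: brute-force time stepping, textbook
closed forms and 1-D cumulative unwrapping.  None of it shares code with
the package modules it checks.
"""

from __future__ import annotations

import numpy as np


def bloch_time_stepped(p, t1, m0=1.0, n_periods=80):
    """Brute-force periodic Bloch simulation of one (ME-)MP2RAGE period.

    Steps the longitudinal magnetization line by line (instantaneous
    rotation, then relaxation over one line period) for ``n_periods``
    repetitions so the steady state is reached by convergence, and reads
    the transverse signal at the k-space center excitation of each block.
    Returns ``(s1, s2, mz_before_inversion)`` without T2* decay or gain.
    """
    from memp2rage.acquisition import derive_gaps, n_lines_before_center

    t_a, t_b, t_c = derive_gaps(p)
    nb = n_lines_before_center(p)
    a1 = np.deg2rad(p.effective_alpha_1)
    a2 = np.deg2rad(p.effective_alpha_2)

    def relax(mz, tau):
        e = np.exp(-tau / t1)
        return mz * e + m0 * (1.0 - e)

    mz = m0
    s1 = s2 = mz_ss = None
    for _ in range(n_periods):
        mz_ss = mz
        mz = (1.0 - 2.0 * p.inv_efficiency) * mz
        mz = relax(mz, t_a)
        for line in range(p.n_lines):
            if line == nb:
                s1 = mz * np.sin(a1)
            mz = relax(mz * np.cos(a1), p.tr_gre)
        mz = relax(mz, t_b)
        for line in range(p.n_lines):
            if line == nb:
                s2 = mz * np.sin(a2)
            mz = relax(mz * np.cos(a2), p.tr_gre)
        mz = relax(mz, t_c)
    return s1, s2, mz_ss


def loglinear_t2star_sd(te, t2star, noise_sd, s0=1.0):
    """First-order propagation of magnitude noise through the log-linear fit.

    For unweighted OLS of ln(S) on TE with independent magnitude noise of
    SD ``noise_sd``: Var(ln S_i) = (noise_sd / S_i)^2, the slope variance
    follows from the OLS influence coefficients, and the delta method
    maps the slope b = -1/T2* to sd(T2*) = T2*^2 * sd(b).
    """
    te = np.asarray(te, dtype=float)
    s = s0 * np.exp(-te / t2star)
    sigma_ln = noise_sd / s
    c = (te - te.mean()) / np.sum((te - te.mean()) ** 2)
    var_b = np.sum(c**2 * sigma_ln**2)
    return t2star**2 * np.sqrt(var_b)


def itoh_unwrap_1d(wrapped, axis=0):
    """Cumulative-difference (Itoh) phase unwrapping along one axis."""
    return np.unwrap(np.asarray(wrapped, dtype=float), axis=axis)


def sphere_dipole_field(shape, center, radius, chi, voxel_size, z_axis=2):
    """Analytic z-field of a uniformly magnetized sphere, in units of chi.

    Outside: (chi/3) (R/r)^3 (3 cos^2 theta - 1); inside: 0 (the Lorentz
    term cancels the demagnetizing field for the spectral convention with
    D(0) = 0 ... up to the mean offset, which the caller removes).
    """
    grids = np.meshgrid(*[(np.arange(n) - c) * v
                          for n, c, v in zip(shape, center, voxel_size)],
                        indexing="ij", sparse=True)
    r2 = sum(g**2 for g in grids)
    r = np.sqrt(r2)
    cos2 = np.zeros(shape)
    nz = r > 0
    z = np.broadcast_to(grids[z_axis], shape)
    cos2[nz] = (z[nz] / r[nz]) ** 2
    field = np.zeros(shape)
    out = r > radius
    field[out] = (chi / 3.0) * (radius / r[out]) ** 3 * (3.0 * cos2[out] - 1.0)
    return field


def monotonic_runs_bruteforce(values):
    """All maximal strictly monotonic index runs of a 1-D sequence."""
    values = np.asarray(values)
    runs = []
    i = 0
    n = len(values)
    while i < n - 1:
        step = np.sign(values[i + 1] - values[i])
        if step == 0:
            i += 1
            continue
        j = i
        while j < n - 1 and np.sign(values[j + 1] - values[j]) == step:
            j += 1
        runs.append((i, j))
        i = j
    return runs
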