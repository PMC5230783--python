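"""T1 estimation from the uniform image via a tabulated lookup.

rho(T1) is tabulated on a fine grid from the closed-form signal model and
restricted to its largest strictly monotonic branch containing the
nominal white/gray-matter midpoint T1 ~ 1.6 s; on that branch the map is
invertible and T1 estimates follow by linear interpolation of the inverse.
rho values falling outside the branch (e.g. very long-T1 CSF when the
protocol's invertible range ends near 3 s) are clamped to the nearest
branch endpoint and flagged, mimicking the systematic underestimation
such protocols exhibit rather than dropping voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import ProtocolParams
from .signal_model import rho_of_t1
from .volumes import VolumeMap

__all__ = ["RhoLookup", "build_lookup", "invert_rho", "b1_sensitivity_curves",
           "T1_ANCHOR"]

# midpoint of the expected WM (~1.2 s) and GM (~2.0 s) values; the
# monotonic branch used for inversion must contain it
T1_ANCHOR = 1.6


@dataclass(frozen=True)
class RhoLookup:
    """Tabulated rho(T1) with its invertible monotonic branch.

    ``t1_grid``/``rho_grid`` cover the full tabulated range;
    ``branch`` = (i, j) are inclusive grid indices of the selected
    strictly monotonic branch and ``valid_range`` its T1 endpoints in
    seconds.  ``protocol_fingerprint`` ties the table to the protocol
    that generated it.
    """

    t1_grid: np.ndarray
    rho_grid: np.ndarray
    branch: tuple[int, int]
    protocol_fingerprint: str

    @property
    def valid_range(self) -> tuple[float, float]:
        i, j = self.branch
        return float(self.t1_grid[i]), float(self.t1_grid[j])

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.t1_grid)))

    def branch_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(rho, t1) on the branch, sorted by ascending rho."""
        i, j = self.branch
        rho = self.rho_grid[i : j + 1]
        t1 = self.t1_grid[i : j + 1]
        if rho[0] > rho[-1]:
            rho, t1 = rho[::-1], t1[::-1]
        return rho, t1

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t1_grid, self.rho_grid]),
                   delimiter=",", header="t1_s,rho", comments="")


def _monotonic_runs(rho: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive index ranges of maximal strictly monotonic runs."""
    d = np.sign(np.diff(rho))
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(d)):
        if d[i] != d[i - 1] or d[i] == 0:
            if d[i - 1] != 0:
                runs.append((start, i))
            start = i
    if len(d) and d[-1] != 0:
        runs.append((start, len(d)))
    return runs


def build_lookup(p: ProtocolParams, t1_min: float = 0.1, t1_max: float = 5.0,
                 step: float = 1e-3) -> RhoLookup:
    """Tabulate rho(T1) and locate its invertible branch.

    The branch is the longest strictly monotonic run of the tabulated
    curve whose T1 interval contains :data:`T1_ANCHOR`; an error is
    raised if no monotonic run covers it.
    """
    if not 0 < t1_min < t1_max:
        raise ValueError("need 0 < t1_min < t1_max")
    n = int(round((t1_max - t1_min) / step)) + 1
    t1_grid = t1_min + step * np.arange(n)
    rho = np.asarray(rho_of_t1(p, t1_grid), dtype=float)
    anchor = min(max(T1_ANCHOR, t1_min), t1_max)
    candidates = [(i, j) for i, j in _monotonic_runs(rho)
                  if t1_grid[i] <= anchor <= t1_grid[j]]
    if not candidates:
        raise ValueError(
            f"rho(T1) has no strictly monotonic branch containing {anchor} s "
            f"for this protocol; it cannot be inverted for T1"
        )
    branch = max(candidates, key=lambda ij: ij[1] - ij[0])
    return RhoLookup(t1_grid=t1_grid, rho_grid=rho, branch=branch,
                     protocol_fingerprint=p.fingerprint())


def invert_rho(rho_map, lut: RhoLookup, expected_fingerprint: str | None = None):
    """Invert a rho map to T1 (seconds) on the lookup's monotonic branch.

    Accepts a :class:`VolumeMap` or a bare array.  Out-of-branch rho is
    clamped to the nearest branch endpoint; a companion boolean array
    flags those voxels.  Returns ``(t1, clamped)`` for arrays or a
    ``(VolumeMap, clamped)`` pair for volumes.
    """
    if expected_fingerprint is not None and expected_fingerprint != lut.protocol_fingerprint:
        raise ValueError("lookup table was built for a different protocol")
    is_vol = isinstance(rho_map, VolumeMap)
    rho = np.asarray(rho_map.data if is_vol else rho_map, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("rho map contains non-finite values")
    rho_b, t1_b = lut.branch_arrays()
    clamped = (rho < rho_b[0]) | (rho > rho_b[-1])
    t1 = np.interp(rho, rho_b, t1_b)
    if is_vol:
        out = rho_map.with_data(t1, units="s", step=f"invert_rho[{lut.protocol_fingerprint}]")
        out.mask = ~clamped if rho_map.mask is None else rho_map.mask & ~clamped
        return out, clamped
    return t1, clamped


def b1_sensitivity_curves(p: ProtocolParams, offsets, t1_min: float = 0.1,
                          t1_max: float = 5.0, step: float = 1e-3) -> dict:
    """Family of rho(T1) curves under fractional B1+ offsets.

    Each offset scales both flip angles by (1 + offset); offset 0
    reproduces the nominal curve exactly.  Returns
    ``{offset: (t1_grid, rho)}``.
    """
    n = int(round((t1_max - t1_min) / step)) + 1
    t1_grid = t1_min + step * np.arange(n)
    curves = {}
    for off in offsets:
        if off <= -1:
            raise ValueError("offset must be > -1")
        curves[float(off)] = (t1_grid, np.asarray(rho_of_t1(p, t1_grid, flip_scale=1.0 + off)))
    return curves
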