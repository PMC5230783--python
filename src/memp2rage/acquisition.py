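"""Acquisition protocols for (ME-)MP2RAGE and ME-FLASH sequences.

A protocol fully parameterizes one sequence repetition: the time between
inversion pulses ``tr_seq``, the k-space-center times ``ti_1``/``ti_2`` of
the two GRE readout blocks, the nominal excitation flip angles, the
intra-block line repetition time ``tr_gre``, the number of k-space lines
per block and the echo train.  Derived quantities are the inter-block gaps
``T_A`` (inversion pulse to start of block 1), ``T_B`` (between blocks)
and ``T_C`` (end of block 2 to the next inversion).

The position of the k-space center inside a block is controlled by
``center_fraction``: the fraction of a block's lines acquired before the
center line.  With linear phase encoding and full k-space coverage this is
0.5; partial-Fourier acquisitions shift the center earlier (6/8 partial
Fourier corresponds to 1/3).
"""

from __future__ import annotations

import enum
import hashlib
import math
from dataclasses import dataclass, asdict, replace
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "SequenceKind",
    "ProtocolParams",
    "InfeasibleTimingError",
    "echo_times",
    "derive_gaps",
    "total_time",
    "n_lines_before_center",
    "load_protocol",
    "save_protocol",
    "bundled_protocol",
    "bundled_protocol_names",
]


class SequenceKind(str, enum.Enum):
    ME_MP2RAGE = "me_mp2rage"
    MP2RAGE = "mp2rage"
    ME_FLASH = "me_flash"

    @property
    def has_inversion(self) -> bool:
        return self is not SequenceKind.ME_FLASH


class InfeasibleTimingError(ValueError):
    """Raised when the requested block timings do not fit in the period."""


@dataclass(frozen=True)
class ProtocolParams:
    """Full parameterization of one acquisition protocol.

    All times are in seconds, flip angles in degrees, bandwidth in Hz per
    pixel.  ``inv_efficiency`` is the adiabatic inversion efficiency
    eta = (1/2)[1 - Mz(0+)/Mz(0-)]; 1 means a perfect inversion.
    ``flip_accuracy`` is the B1+ scale factor converting nominal to
    effective flip angles (effective = flip_accuracy * nominal); it is
    applied before any signal computation.  ``bandwidth`` is metadata only
    and never enters the signal model.
    """

    sequence_kind: SequenceKind
    tr_seq: Optional[float] = None
    ti_1: Optional[float] = None
    ti_2: Optional[float] = None
    alpha_1: float = 0.0
    alpha_2: float = 0.0
    tr_gre: float = 0.0
    n_lines: int = 0
    n_echoes: int = 1
    te_first: float = 0.0
    delta_te: float = 0.0
    bandwidth: Optional[float] = None
    inv_efficiency: float = 1.0
    flip_accuracy: float = 1.0
    center_fraction: float = 0.5

    def __post_init__(self) -> None:
        kind = SequenceKind(self.sequence_kind)
        object.__setattr__(self, "sequence_kind", kind)
        if self.n_echoes < 1:
            raise ValueError("n_echoes must be >= 1")
        if self.te_first <= 0:
            raise ValueError("te_first must be positive")
        if self.n_echoes > 1 and self.delta_te <= 0:
            raise ValueError("delta_te must be positive for multi-echo trains")
        if self.tr_gre <= 0:
            raise ValueError("tr_gre must be positive")
        if not 0.0 <= self.inv_efficiency <= 1.0:
            raise ValueError("inv_efficiency must lie in [0, 1]")
        if not 0.0 < self.center_fraction < 1.0:
            raise ValueError("center_fraction must lie in (0, 1)")
        if kind.has_inversion:
            if self.tr_seq is None or self.ti_1 is None or self.ti_2 is None:
                raise ValueError(f"{kind.value} requires tr_seq, ti_1 and ti_2")
            if not (0 < self.ti_1 < self.ti_2 < self.tr_seq):
                raise ValueError("timings must satisfy 0 < ti_1 < ti_2 < tr_seq")
            if self.n_lines < 0:
                raise ValueError("n_lines must be non-negative")
        last_te = self.te_first + (self.n_echoes - 1) * self.delta_te
        if last_te >= self.tr_gre:
            raise ValueError(
                f"echo train (last TE {last_te * 1e3:.2f} ms) does not fit in "
                f"one line period (tr_gre {self.tr_gre * 1e3:.2f} ms)"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def effective_alpha_1(self) -> float:
        """Effective first-block flip angle in degrees (B1+ scaled)."""
        return self.alpha_1 * self.flip_accuracy

    @property
    def effective_alpha_2(self) -> float:
        return self.alpha_2 * self.flip_accuracy

    def with_flip_scale(self, scale: float) -> "ProtocolParams":
        """Copy with an extra multiplicative B1+ offset on the flip angles."""
        return replace(self, flip_accuracy=self.flip_accuracy * scale)

    def fingerprint(self) -> str:
        """Stable identifier for lookup-table/protocol consistency checks."""
        payload = dict(asdict(self))
        payload["sequence_kind"] = self.sequence_kind.value
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:16]


def n_lines_before_center(p: ProtocolParams) -> int:
    """Number of k-space lines acquired before the center of a GRE block."""
    # round-half-up keeps the split deterministic for the common n/2 case
    return int(math.floor(p.center_fraction * p.n_lines + 0.5))


def echo_times(p: ProtocolParams) -> list[float]:
    """Echo times of the uniform echo train, in seconds, strictly increasing."""
    return [p.te_first + i * p.delta_te for i in range(p.n_echoes)]


def derive_gaps(p: ProtocolParams) -> tuple[float, float, float]:
    """Inter-block gaps (T_A, T_B, T_C) in seconds.

    T_A runs from the inversion pulse to the first excitation of block 1,
    T_B between the two blocks, T_C from the end of block 2 to the next
    inversion.  The k-space center of block ``j`` falls at ``ti_j``, i.e.
    ``n_before`` line periods after the block starts.

    Raises
    ------
    InfeasibleTimingError
        If any gap would be negative, naming the offending gap.
    """
    if not p.sequence_kind.has_inversion:
        raise ValueError("gaps are only defined for inversion-prepared sequences")
    nb = n_lines_before_center(p)
    t_a = p.ti_1 - nb * p.tr_gre
    t_b = p.ti_2 - p.ti_1 - p.n_lines * p.tr_gre
    t_c = p.tr_seq - p.ti_2 - (p.n_lines - nb) * p.tr_gre
    for name, val in (("T_A", t_a), ("T_B", t_b), ("T_C", t_c)):
        if val < 0:
            raise InfeasibleTimingError(
                f"{name} = {val * 1e3:.1f} ms is negative: the GRE blocks do "
                f"not fit between the inversion pulses for this protocol"
            )
    return t_a, t_b, t_c


def total_time(p: ProtocolParams, n_outer: int) -> float:
    """Total acquisition time: one period per outer phase-encoding step."""
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    if p.tr_seq is None:
        raise ValueError("total_time requires an inversion-prepared protocol")
    return p.tr_seq * n_outer


# -- serialization ----------------------------------------------------------

def _to_dict(p: ProtocolParams) -> dict:
    d = asdict(p)
    d["sequence_kind"] = p.sequence_kind.value
    return {k: v for k, v in d.items() if v is not None}


def save_protocol(p: ProtocolParams, path) -> None:
    """Write a protocol as a flat YAML mapping (seconds / degrees / Hz-px)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(p), fh, sort_keys=True)


def load_protocol(path) -> ProtocolParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ProtocolParams(**data)


def _bundled_table() -> dict:
    text = resources.files("memp2rage.data").joinpath("protocols.yaml").read_text()
    return yaml.safe_load(text)


def bundled_protocol_names() -> list[str]:
    return sorted(_bundled_table())


def bundled_protocol(name: str) -> ProtocolParams:
    """Load one of the packaged reference protocols by name.

    ``me_mp2rage``, ``mp2rage`` and ``me_flash`` reproduce the published
    0.6 mm protocols of the sequence-comparison study this package models;
    ``mp2rage_sim`` is the inversion-time variant used in its precision
    simulations.
    """
    table = _bundled_table()
    if name not in table:
        raise KeyError(f"unknown bundled protocol {name!r}; have {sorted(table)}")
    return ProtocolParams(**table[name])
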