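"""In-memory volume container and NIfTI I/O.

Volumes are plain numpy grids with voxel geometry, a units tag, an
optional validity mask and a provenance trail.  On disk they are NIfTI-1
files (RAS, voxel sizes taken from the header, no resampling on load).
Complex data is stored as separate magnitude and phase files, with phase
in radians wrapped to (-pi, pi].  The units tag lives in the header
``descrip`` field; the provenance list is carried as a JSON header
extension so it survives a round trip verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = ["VolumeMap", "read_volume", "write_volume", "read_complex_volume", "write_complex_volume", "wrap_phase"]

_PROV_ECODE = 6  # NIfTI 'comment' extension


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase to the (-pi, pi] interval."""
    return np.pi - np.mod(np.pi - np.asarray(phase), 2.0 * np.pi)


@dataclass
class VolumeMap:
    """A 3-D (or echo-stacked 4-D) scalar or complex volume.

    ``voxel_size`` is in mm per axis (of the three spatial axes); ``units``
    is a free-text tag such as ``s``, ``ms``, ``ppb``, ``rad`` or ``a.u.``.
    ``provenance`` records the operations applied, oldest first.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = "a.u."
    mask: Optional[np.ndarray] = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[-3:] and self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray, units: Optional[str] = None, step: Optional[str] = None) -> "VolumeMap":
        out = replace(self, data=np.asarray(data), units=units or self.units,
                      provenance=list(self.provenance))
        if step:
            out.provenance.append(step)
        return out


def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_volume(v: VolumeMap, path) -> None:
    """Write a real-valued volume as NIfTI-1 with units and provenance."""
    data = np.asarray(v.data)
    if np.iscomplexobj(data):
        raise ValueError("complex volumes must be written as magnitude/phase pairs")
    img = nib.Nifti1Image(data.astype(np.float64), _affine(v.voxel_size))
    img.header["descrip"] = f"units={v.units}".encode()[:79]
    payload = json.dumps({"provenance": v.provenance}).encode()
    img.header.extensions.append(nib.nifti1.Nifti1Extension(_PROV_ECODE, payload))
    nib.save(img, str(path))


def read_volume(path) -> VolumeMap:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"volume not found: {path}") from None
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"cannot read {path}: non-positive voxel size in header")
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    units = descrip.split("units=", 1)[1] if "units=" in descrip else "a.u."
    provenance: list[str] = []
    for ext in img.header.extensions:
        if ext.get_code() == _PROV_ECODE:
            try:
                provenance = json.loads(bytes(ext.get_content()))["provenance"]
            except (ValueError, KeyError, TypeError):
                pass
    return VolumeMap(data=np.asarray(img.dataobj, dtype=np.float64),
                     voxel_size=tuple(float(z) for z in zooms),
                     units=units, provenance=provenance)


def write_complex_volume(v: VolumeMap, mag_path, phase_path) -> None:
    """Write complex data as a magnitude file plus a phase (radians) file."""
    data = np.asarray(v.data)
    mag = replace(v, data=np.abs(data), units=v.units)
    ph = replace(v, data=wrap_phase(np.angle(data)), units="rad")
    write_volume(mag, mag_path)
    write_volume(ph, phase_path)


def read_complex_volume(mag_path, phase_path) -> VolumeMap:
    mag = read_volume(mag_path)
    ph = read_volume(phase_path)
    if mag.data.shape != ph.data.shape:
        raise ValueError("magnitude and phase volumes are not congruent")
    return replace(mag, data=mag.data * np.exp(1j * ph.data))
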