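"""3D CT volume container and on-disk formats.

A :class:`CTVolume` is a 3D grid of Hounsfield units (HU) indexed
``[z, y, x]`` (slice, row, column) with square in-plane pixels of side
``pixel_size_xy`` mm and axial slice thickness ``slice_thickness`` mm.
Voxel ``(iz, iy, ix)`` occupies the half-open box whose corner is at
``origin + (ix, iy, iz) * (l, w, t)``; its center is offset by half a
voxel in each axis.  Volumes round-trip through NIfTI (via nibabel) and
through a raw little-endian float32 file with a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "read_volume"]


@dataclass
class CTVolume:
    """A 3D HU grid with voxel geometry and provenance metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values, indexed ``[z, y, x]``.
    pixel_size_xy : float
        In-plane pixel side in mm (square pixels: length ``l`` equals
        width ``w``).
    slice_thickness : float
        Nominal slice thickness ``t`` in mm.
    origin : tuple of float
        World-space (x, y, z) mm position of the corner of voxel
        ``(0, 0, 0)``.
    provenance : dict
        Free-form metadata recording how the volume was synthesized
        (kernel, FOV, averaging chain, seeds).
    """

    data: np.ndarray
    pixel_size_xy: float
    slice_thickness: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3D array with all dims >= 1")
        if not (self.pixel_size_xy > 0 and self.slice_thickness > 0):
            raise ValueError("voxel dimensions must be positive")
        self.origin = tuple(float(v) for v in self.origin)

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, ``l * w * t`` in mm^3."""
        return self.pixel_size_xy * self.pixel_size_xy * self.slice_thickness

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-space center coordinates along each axis: (z, y, x) mm."""
        nz, ny, nx = self.data.shape
        l = self.pixel_size_xy
        t = self.slice_thickness
        zc = self.origin[2] + (np.arange(nz) + 0.5) * t
        yc = self.origin[1] + (np.arange(ny) + 0.5) * l
        xc = self.origin[0] + (np.arange(nx) + 0.5) * l
        return zc, yc, xc

    def with_data(self, data: np.ndarray, *, slice_thickness: float | None = None,
                  origin: tuple[float, float, float] | None = None,
                  note: str | None = None) -> "CTVolume":
        """New volume sharing geometry, with ``data`` and a provenance note."""
        prov = dict(self.provenance)
        if note:
            chain = list(prov.get("chain", []))
            chain.append(note)
            prov["chain"] = chain
        return CTVolume(
            data=data,
            pixel_size_xy=self.pixel_size_xy,
            slice_thickness=self.slice_thickness if slice_thickness is None else slice_thickness,
            origin=self.origin if origin is None else origin,
            provenance=prov,
        )

    def crop(self, z: slice = slice(None), y: slice = slice(None),
             x: slice = slice(None)) -> "CTVolume":
        """Crop by index slices, shifting the origin accordingly."""
        zi, yi, xi = (s.indices(n) for s, n in zip((z, y, x), self.data.shape))
        ox = self.origin[0] + xi[0] * self.pixel_size_xy
        oy = self.origin[1] + yi[0] * self.pixel_size_xy
        oz = self.origin[2] + zi[0] * self.slice_thickness
        return self.with_data(self.data[z, y, x], origin=(ox, oy, oz),
                              note=f"crop z={zi} y={yi} x={xi}")

    # -- I/O ----------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI; array stored (x, y, z) with a diagonal affine."""
        affine = np.diag([self.pixel_size_xy, self.pixel_size_xy,
                          self.slice_thickness, 1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(
            np.ascontiguousarray(self.data.T.astype(np.float32)), affine)
        img.header.set_zooms((self.pixel_size_xy, self.pixel_size_xy,
                              self.slice_thickness))
        descrip = json.dumps(self.provenance)[:79]
        img.header["descrip"] = descrip.encode()
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "CTVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.isclose(zooms[0], zooms[1]):
            raise ValueError("NIfTI pixels are not square in-plane")
        data = np.asanyarray(img.dataobj).T  # (x,y,z) -> (z,y,x)
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data=data, pixel_size_xy=float(zooms[0]),
                   slice_thickness=float(zooms[2]), origin=origin,
                   provenance={"source": str(path)})

    def to_raw(self, path: str | Path) -> None:
        """Write raw little-endian float32 (C order, z fastest-outer) plus
        a ``.json`` sidecar with dims, voxel sizes and provenance."""
        path = Path(path)
        self.data.astype("<f4").tofile(path)
        sidecar = {
            "shape_zyx": list(self.data.shape),
            "dtype": "<f4",
            "pixel_size_xy_mm": self.pixel_size_xy,
            "slice_thickness_mm": self.slice_thickness,
            "origin_mm": list(self.origin),
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def from_raw(cls, path: str | Path) -> "CTVolume":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(
            sidecar["shape_zyx"])
        return cls(data=data,
                   pixel_size_xy=sidecar["pixel_size_xy_mm"],
                   slice_thickness=sidecar["slice_thickness_mm"],
                   origin=tuple(sidecar["origin_mm"]),
                   provenance=sidecar.get("provenance", {}))


def read_volume(path: str | Path) -> CTVolume:
    """Load a volume from NIfTI (``.nii``/``.nii.gz``) or raw+sidecar."""
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return CTVolume.from_nifti(path)
    return CTVolume.from_raw(path)
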