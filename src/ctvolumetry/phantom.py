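"""Digital sphere-in-gelatin phantom: specification and voxelization.

The phantom emulated here is a rectangular gelatin block (background
about 37.6 HU) containing acrylic (PMMA, about 118.2 HU) spheres of
eleven diameters, each replicated five times, arranged in horizontal
layers.  The default diameter series is the inch-fraction ladder
1/16" .. 1" (1.5875 mm to 25.4 mm): commercially molded precision
spheres come in inch fractions, and the commonly quoted metric labels
(1.6, 3.2, 6.4, 25.4 mm) are rounded versions of exactly these values.

Voxelization computes, for every voxel, the fraction of its volume
occupied by sphere material and mixes the two HU values linearly —
reproducing the partial-volume effect that threshold-based volumetry
is sensitive to.  Occupancy is evaluated analytically for voxels that
are provably fully inside or outside a sphere and by supersampling on
the boundary shell, so the cost scales with sphere surface area rather
than volume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import CTVolume

__all__ = [
    "SphereSpec", "PhantomSpec", "PlacementError",
    "DEFAULT_DIAMETERS_MM", "BACKGROUND_HU", "SPHERE_HU", "CONTAINER_MM",
    "sphere_true_volume", "pixel_size", "build_phantom_spec", "voxelize",
]

#: Inch-fraction diameter ladder, 1/16" through 1", in mm.
DEFAULT_DIAMETERS_MM: tuple[float, ...] = tuple(
    25.4 * k / 16 for k in (1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16)
)

#: Mean measured HU of the gelatin background and the PMMA spheres.
BACKGROUND_HU: float = 37.6
SPHERE_HU: float = 118.2

#: Container interior (x, y, z) in mm: square base, 40 cm tall.
CONTAINER_MM: tuple[float, float, float] = (152.0, 152.0, 400.0)


class PlacementError(RuntimeError):
    """Raised when spheres cannot be placed without overlap."""


def sphere_true_volume(diameter: float) -> float:
    """Analytic sphere volume (4/3)*pi*r^3 in mm^3 for a diameter in mm."""
    if diameter < 0:
        raise ValueError(f"diameter must be >= 0, got {diameter}")
    r = diameter / 2.0
    return (4.0 / 3.0) * math.pi * r ** 3


def pixel_size(fov_cm: float, matrix: int) -> float:
    """Reconstructed square pixel side in mm: FOV (cm) over matrix size."""
    if fov_cm <= 0 or matrix < 1:
        raise ValueError("fov_cm must be > 0 and matrix >= 1")
    return fov_cm * 10.0 / matrix


@dataclass(frozen=True)
class SphereSpec:
    """One ground-truth sphere: id, diameter (mm), center (x,y,z mm), HU."""

    id: str
    diameter: float
    center: tuple[float, float, float]
    material_hu: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"sphere diameter must be > 0, got {self.diameter}")
        if not math.isfinite(self.material_hu):
            raise ValueError("material_hu must be finite")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def true_volume(self) -> float:
        return sphere_true_volume(self.diameter)


@dataclass
class PhantomSpec:
    """Ground-truth phantom geometry: non-overlapping spheres in a box."""

    spheres: list[SphereSpec]
    background_hu: float = BACKGROUND_HU
    container_dims: tuple[float, float, float] = CONTAINER_MM
    n_sizes: int = 0
    n_replicates: int = 0
    layout_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sizes and self.n_replicates:
            if len(self.spheres) != self.n_sizes * self.n_replicates:
                raise ValueError(
                    f"{len(self.spheres)} spheres but n_sizes*n_replicates = "
                    f"{self.n_sizes * self.n_replicates}")
        for s in self.spheres:
            if math.isclose(s.material_hu, self.background_hu):
                raise ValueError("sphere HU must differ from background HU")
            for c, dim in zip(s.center, self.container_dims):
                if c - s.radius < 0 or c + s.radius > dim:
                    raise ValueError(f"sphere {s.id} extends outside container")
        centers = np.array([s.center for s in self.spheres], dtype=float)
        radii = np.array([s.radius for s in self.spheres], dtype=float)
        for i in range(len(self.spheres)):
            d = np.linalg.norm(centers[i + 1:] - centers[i], axis=1)
            if np.any(d <= radii[i + 1:] + radii[i]):
                j = int(np.argmax(d <= radii[i + 1:] + radii[i])) + i + 1
                raise ValueError(
                    f"spheres {self.spheres[i].id} and {self.spheres[j].id} overlap")

    @property
    def diameters(self) -> list[float]:
        """Sorted unique diameters present in the phantom."""
        return sorted({s.diameter for s in self.spheres})

    # -- manifest serialization --------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        manifest = {
            "background_hu": self.background_hu,
            "container_dims_mm": list(self.container_dims),
            "n_sizes": self.n_sizes,
            "n_replicates": self.n_replicates,
            "layout_seed": self.layout_seed,
            "spheres": [
                {"id": s.id, "diameter_mm": s.diameter,
                 "center_mm": list(s.center), "material_hu": s.material_hu}
                for s in self.spheres
            ],
        }
        text = json.dumps(manifest, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PhantomSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        m = json.loads(text)
        spheres = [
            SphereSpec(id=s["id"], diameter=s["diameter_mm"],
                       center=tuple(s["center_mm"]), material_hu=s["material_hu"])
            for s in m["spheres"]
        ]
        return cls(spheres=spheres, background_hu=m["background_hu"],
                   container_dims=tuple(m["container_dims_mm"]),
                   n_sizes=m["n_sizes"], n_replicates=m["n_replicates"],
                   layout_seed=m.get("layout_seed"))


def build_phantom_spec(
    layout_seed: int,
    diameters: list[float] | tuple[float, ...] = DEFAULT_DIAMETERS_MM,
    n_replicates: int = 5,
    container: tuple[float, float, float] = CONTAINER_MM,
    background_hu: float = BACKGROUND_HU,
    sphere_hu: float = SPHERE_HU,
    clearance: float = 5.0,
    edge_margin: float = 3.0,
    z_jitter: float = 3.0,
    max_tries: int = 2000,
) -> PhantomSpec:
    """Place ``n_replicates`` layers, each holding one sphere per diameter.

    Layers are stacked along z at even spacing; each layer's z position
    receives a seeded random offset (up to ``z_jitter`` mm) so that the
    phase of each replicate relative to the slice grid varies, as it
    would for spheres set by hand in poured gelatin.  In-plane positions
    are drawn by rejection sampling with a minimum surface-to-surface
    ``clearance``; every layer therefore has a different arrangement.

    Raises :class:`PlacementError` if a sphere cannot be placed within
    ``max_tries`` draws, which signals a container too small for the
    requested diameters.
    """
    diameters = list(diameters)
    if not diameters or any(d <= 0 for d in diameters):
        raise ValueError("diameters must be non-empty and positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(layout_seed)
    cx, cy, cz = container

    spheres: list[SphereSpec] = []
    if len(diameters) == 1 and n_replicates == 1:
        # Degenerate layout: a single sphere sits at the container center.
        d = diameters[0]
        spheres.append(SphereSpec(id=f"r1-d{d:g}mm", diameter=d,
                                  center=(cx / 2, cy / 2, cz / 2),
                                  material_hu=sphere_hu))
        return PhantomSpec(spheres=spheres, background_hu=background_hu,
                           container_dims=container, n_sizes=1, n_replicates=1,
                           layout_seed=layout_seed)

    layer_pitch = cz / n_replicates
    order = sorted(diameters, reverse=True)  # place large spheres first
    for rep in range(n_replicates):
        z0 = (rep + 0.5) * layer_pitch + rng.uniform(-z_jitter, z_jitter)
        placed: list[tuple[float, float, float]] = []  # (x, y, r)
        for d in order:
            r = d / 2.0
            lo, hi_x, hi_y = r + edge_margin, cx - r - edge_margin, cy - r - edge_margin
            if lo >= hi_x or lo >= hi_y:
                raise PlacementError(
                    f"container too small for a {d} mm sphere with margins")
            for _ in range(max_tries):
                x = rng.uniform(lo, hi_x)
                y = rng.uniform(lo, hi_y)
                if all((x - px) ** 2 + (y - py) ** 2 >= (r + pr + clearance) ** 2
                       for px, py, pr in placed):
                    placed.append((x, y, r))
                    spheres.append(SphereSpec(
                        id=f"r{rep + 1}-d{d:g}mm", diameter=d,
                        center=(x, y, z0), material_hu=sphere_hu))
                    break
            else:
                raise PlacementError(
                    f"could not place {d} mm sphere in layer {rep + 1}: "
                    "container too small for the requested layout")

    return PhantomSpec(spheres=spheres, background_hu=background_hu,
                       container_dims=container, n_sizes=len(diameters),
                       n_replicates=n_replicates, layout_seed=layout_seed)


def voxelize(
    spec: PhantomSpec,
    pixel_size_xy: float,
    native_thickness: float,
    supersample: int = 8,
    matrix: int | None = None,
) -> CTVolume:
    """Render a phantom onto a noiseless native-resolution HU grid.

    Each voxel's HU is ``bg + occupancy * (sphere_hu - bg)`` where
    ``occupancy`` is the fraction of the voxel inside sphere material,
    estimated on a ``supersample``^3 subgrid for boundary voxels.  With
    ``matrix`` given, the in-plane grid is ``matrix`` pixels square
    (the reconstruction field of view) centered on the container;
    otherwise the grid hugs the container.  The z grid always starts at
    the container bottom (world z = 0).
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if pixel_size_xy <= 0 or native_thickness <= 0:
        raise ValueError("voxel dimensions must be positive")
    cx, cy, cz = spec.container_dims
    l, t = float(pixel_size_xy), float(native_thickness)

    if matrix is not None:
        nx = ny = int(matrix)
        ox = cx / 2 - nx * l / 2
        oy = cy / 2 - ny * l / 2
    else:
        nx = math.ceil(cx / l)
        ny = math.ceil(cy / l)
        ox = oy = 0.0
    nz = math.ceil(cz / t)
    if max(nx, ny, nz) > 4096 or nx < 1 or ny < 1 or nz < 1:
        raise ValueError(f"grid {nx}x{ny}x{nz} not representable")

    data = np.full((nz, ny, nx), spec.background_hu, dtype=np.float32)
    origin = (ox, oy, 0.0)
    half_diag = 0.5 * math.sqrt(l * l + l * l + t * t)
    # Subvoxel sample offsets relative to the voxel corner.
    off = (np.arange(supersample) + 0.5) / supersample
    sub = supersample ** 3

    for s in spec.spheres:
        r = s.radius
        sx, sy, sz = s.center
        ix0 = max(0, int(np.floor((sx - r - ox) / l)) - 1)
        ix1 = min(nx, int(np.ceil((sx + r - ox) / l)) + 1)
        iy0 = max(0, int(np.floor((sy - r - oy) / l)) - 1)
        iy1 = min(ny, int(np.ceil((sy + r - oy) / l)) + 1)
        iz0 = max(0, int(np.floor((sz - r) / t)) - 1)
        iz1 = min(nz, int(np.ceil((sz + r) / t)) + 1)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue

        zc = (np.arange(iz0, iz1) + 0.5) * t - sz
        yc = oy + (np.arange(iy0, iy1) + 0.5) * l - sy
        xc = ox + (np.arange(ix0, ix1) + 0.5) * l - sx
        dist = np.sqrt(zc[:, None, None] ** 2 + yc[None, :, None] ** 2
                       + xc[None, None, :] ** 2)

        occ = np.zeros(dist.shape, dtype=np.float32)
        occ[dist <= r - half_diag] = 1.0
        shell = (dist > r - half_diag) & (dist < r + half_diag)
        if np.any(shell):
            kz, ky, kx = np.nonzero(shell)
            # Corner coordinates of the shell voxels, relative to center.
            cz_ = (kz + iz0) * t - sz
            cy_ = oy + (ky + iy0) * l - sy
            cx_ = ox + (kx + ix0) * l - sx
            counts = np.empty(len(kz), dtype=np.int64)
            # Chunk the shell so the (K, s, s, s) distance array stays small.
            step = max(1, 2 ** 22 // sub)
            for a in range(0, len(kz), step):
                b = a + step
                zz = cz_[a:b, None] + off[None, :] * t  # (K, s)
                yy = cy_[a:b, None] + off[None, :] * l
                xx = cx_[a:b, None] + off[None, :] * l
                d2 = (zz[:, :, None, None] ** 2 + yy[:, None, :, None] ** 2
                      + xx[:, None, None, :] ** 2)
                counts[a:b] = (d2 <= r * r).reshape(-1, sub).sum(axis=1)
            occ[kz, ky, kx] = counts / sub

        data[iz0:iz1, iy0:iy1, ix0:ix1] += (
            occ * (s.material_hu - spec.background_hu))

    return CTVolume(
        data=data, pixel_size_xy=l, slice_thickness=t, origin=origin,
        provenance={"stage": "voxelize", "supersample": supersample,
                    "layout_seed": spec.layout_seed,
                    "n_spheres": len(spec.spheres)})
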