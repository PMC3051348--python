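"""Component volumetry and matching against ground-truth spheres.

Measured volume follows the voxel-counting rule ``V_CT = N_V * l * w * t``
(count of voxels carrying a label times the volume of one voxel).
Components are attributed to ground-truth spheres by nearest center
within a gate of one sphere radius plus one voxel diagonal; spheres
with no component inside their gate are recorded as non-detections,
which downstream statistics exclude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import PhantomSpec
from .segmentation import LabeledVolume

__all__ = [
    "ComponentMeasurement", "SphereMeasurement",
    "measure_components", "match_to_spheres", "percent_error",
    "detection_rate", "measurements_to_frame",
]


@dataclass(frozen=True)
class ComponentMeasurement:
    """One labeled component: voxel count, volume and centroid (mm)."""

    label: int
    n_voxels: int
    volume_mm3: float
    centroid: tuple[float, float, float]  # world (x, y, z) mm


@dataclass(frozen=True)
class SphereMeasurement:
    """Ground-truth sphere matched (or not) to a measured component."""

    sphere_id: str
    true_diameter: float
    v_true: float
    detected: bool
    v_ct: float | None = None
    percent_error: float | None = None
    n_fragments: int = 0       # extra components inside this sphere's gate
    condition: dict | None = None

    def __post_init__(self) -> None:
        if not self.detected and (self.v_ct is not None
                                  or self.percent_error is not None):
            raise ValueError("non-detections carry no measured volume")


def percent_error(v_ct: float, v_true: float) -> float:
    """Signed percent error ``(V_CT - V_true) / V_true * 100``."""
    if v_true <= 0:
        raise ValueError(f"V_true must be > 0, got {v_true}")
    return (v_ct - v_true) / v_true * 100.0


def measure_components(labeled: LabeledVolume) -> list[ComponentMeasurement]:
    """Per-label voxel count, volume (``N_V * l * w * t``) and centroid."""
    n = labeled.n_objects
    if n == 0:
        return []
    flat = labeled.labels.ravel()
    pos = np.flatnonzero(flat)
    vals = flat[pos]
    counts = np.bincount(vals, minlength=n + 1)

    nz, ny, nx = labeled.labels.shape
    iz, rem = np.divmod(pos, ny * nx)
    iy, ix = np.divmod(rem, nx)
    l = labeled.pixel_size_xy
    t = labeled.slice_thickness
    ox, oy, oz = labeled.origin
    sx = np.bincount(vals, weights=ox + (ix + 0.5) * l, minlength=n + 1)
    sy = np.bincount(vals, weights=oy + (iy + 0.5) * l, minlength=n + 1)
    sz = np.bincount(vals, weights=oz + (iz + 0.5) * t, minlength=n + 1)

    out = []
    vox = labeled.voxel_volume
    for lab in range(1, n + 1):
        c = int(counts[lab])
        if c == 0:
            raise ValueError(f"label {lab} has no voxels; labels not compact")
        out.append(ComponentMeasurement(
            label=lab, n_voxels=c, volume_mm3=c * vox,
            centroid=(sx[lab] / c, sy[lab] / c, sz[lab] / c)))
    return out


def match_to_spheres(
    components: list[ComponentMeasurement],
    spec: PhantomSpec,
    *,
    voxel_diagonal: float,
    condition: dict | None = None,
) -> list[SphereMeasurement]:
    """Assign components to ground-truth spheres and flag non-detections.

    A component belongs to the sphere whose center is nearest to the
    component centroid, provided the distance is within that sphere's
    radius plus ``voxel_diagonal`` (the matching gate).  Exact distance
    ties go to the lower sphere id (list order).  When several
    components fall in one gate the largest is kept as the measurement
    and the rest are counted as fragments.
    """
    centers = np.array([s.center for s in spec.spheres], dtype=float)
    gates = np.array([s.radius + voxel_diagonal for s in spec.spheres])

    assigned: dict[int, list[ComponentMeasurement]] = {}
    for comp in components:
        d = np.linalg.norm(centers - np.asarray(comp.centroid), axis=1)
        order = np.lexsort((np.arange(len(d)), d))  # distance, then sphere id
        best = order[0]
        if d[best] <= gates[best]:
            assigned.setdefault(int(best), []).append(comp)

    out = []
    for i, s in enumerate(spec.spheres):
        comps = assigned.get(i)
        if not comps:
            out.append(SphereMeasurement(
                sphere_id=s.id, true_diameter=s.diameter, v_true=s.true_volume,
                detected=False, condition=condition))
            continue
        comps = sorted(comps, key=lambda c: (-c.volume_mm3, c.label))
        main = comps[0]
        out.append(SphereMeasurement(
            sphere_id=s.id, true_diameter=s.diameter, v_true=s.true_volume,
            detected=True, v_ct=main.volume_mm3,
            percent_error=percent_error(main.volume_mm3, s.true_volume),
            n_fragments=len(comps) - 1, condition=condition))
    return out


def detection_rate(measurements: list[SphereMeasurement],
                   diameter: float) -> float:
    """Fraction of measurements at ``diameter`` that were detected."""
    at = [m for m in measurements
          if np.isclose(m.true_diameter, diameter, rtol=1e-6, atol=1e-6)]
    if not at:
        raise ValueError(f"no measurements at diameter {diameter} mm")
    return sum(m.detected for m in at) / len(at)


def measurements_to_frame(measurements: list[SphereMeasurement]) -> pd.DataFrame:
    """Tidy table: one row per sphere x condition."""
    rows = []
    for m in measurements:
        row = {
            "sphere_id": m.sphere_id,
            "diameter_mm": m.true_diameter,
            "v_true_mm3": m.v_true,
            "detected": m.detected,
            "v_ct_mm3": m.v_ct if m.detected else np.nan,
            "percent_error": m.percent_error if m.detected else np.nan,
            "n_fragments": m.n_fragments,
        }
        if m.condition:
            row.update(m.condition)
        rows.append(row)
    return pd.DataFrame(rows)
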