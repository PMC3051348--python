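"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` drives the whole study: build the digital
phantom, voxelize it at each field of view, apply each reconstruction
kernel, synthesize every slice thickness, calibrate the segmentation
threshold on designated calibration cases, segment and measure every
condition, and hand the tidy measurement table to the accuracy model.
Everything is deterministic given the config seed; a short hash of the
canonical config is stamped into every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from .acquisition import DEFAULT_KERNELS, KernelModel, SliceAveragingPlan, \
    apply_kernel, average_slices
from .measurement import SphereMeasurement, match_to_spheres, \
    measure_components, measurements_to_frame
from .phantom import BACKGROUND_HU, CONTAINER_MM, DEFAULT_DIAMETERS_MM, \
    SPHERE_HU, PhantomSpec, build_phantom_spec, pixel_size, \
    sphere_true_volume, voxelize
from .segmentation import SegmentationParams, segment
from .stats import VolumetryAccuracyModel, VolumetryAccuracyResults
from .volume import CTVolume

__all__ = ["ExperimentConfig", "RunResult", "run_experiment", "make_fixture"]

log = logging.getLogger("ctvolumetry")


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class ExperimentConfig:
    """Full description of one simulated phantom study."""

    # phantom
    diameters_mm: tuple[float, ...] = DEFAULT_DIAMETERS_MM
    n_replicates: int = 5
    container_mm: tuple[float, float, float] = CONTAINER_MM
    background_hu: float = BACKGROUND_HU
    sphere_hu: float = SPHERE_HU
    clearance_mm: float = 5.0
    # acquisition grid
    fovs_cm: tuple[float, ...] = (20.0, 30.0, 40.0)
    kernels: dict[str, KernelModel] = field(
        default_factory=lambda: dict(DEFAULT_KERNELS))
    thickness_factors: tuple[int, ...] = (1, 2, 4, 8)
    native_thickness_mm: float = 0.625
    matrix: int = 512
    supersample: int = 8
    # segmentation
    threshold: float | str = 93.0          # HU, or "calibrate"
    min_volume_mm3: float | None = None    # None -> 10% of smallest analyzed
    min_neighbors: int = 3
    connectivity: str = "full-26"
    neighbor_connectivity: str = "full-26"
    exclude_smallest: bool = True
    # calibration
    calibration_thresholds: tuple[float, ...] = (90.0, 100.0, 110.0)
    calibration_cases: tuple[tuple[float, str, float], ...] = (
        (20.0, "standard", 0.625),   # smoothest
        (30.0, "lung", 2.5),         # intermediate
        (40.0, "bone", 5.0),         # noisiest
    )
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.diameters_mm or not self.fovs_cm \
                or not self.kernels or not self.thickness_factors:
            raise ConfigError("all grid lists must be non-empty")
        if any(d <= 0 for d in self.diameters_mm):
            raise ConfigError("diameters must be positive")
        if any(int(f) != f or f < 1 for f in self.thickness_factors):
            raise ConfigError("thickness factors must be positive integers "
                              "(thicknesses are multiples of the native "
                              "thickness)")
        if self.matrix < 8:
            raise ConfigError("matrix too small")
        if self.native_thickness_mm <= 0:
            raise ConfigError("native thickness must be positive")
        if isinstance(self.threshold, str) and self.threshold != "calibrate":
            raise ConfigError(f"threshold must be a number or 'calibrate', "
                              f"got {self.threshold!r}")
        if self.threshold == "calibrate":
            for fov, kern, t_mm in self.calibration_cases:
                factor = t_mm / self.native_thickness_mm
                if fov not in self.fovs_cm or kern not in self.kernels \
                        or int(round(factor)) not in self.thickness_factors:
                    raise ConfigError(
                        f"calibration case ({fov}, {kern}, {t_mm}) is not in "
                        "the experiment grid")

    # -- derived ------------------------------------------------------

    @property
    def thicknesses_mm(self) -> tuple[float, ...]:
        return tuple(f * self.native_thickness_mm
                     for f in self.thickness_factors)

    @property
    def analyzed_diameters(self) -> tuple[float, ...]:
        d = sorted(self.diameters_mm)
        return tuple(d[1:]) if self.exclude_smallest and len(d) > 1 else tuple(d)

    @property
    def excluded_diameters(self) -> tuple[float, ...]:
        d = sorted(self.diameters_mm)
        return (d[0],) if self.exclude_smallest and len(d) > 1 else ()

    def effective_min_volume(self) -> float:
        """Minimum component volume: 10% of the smallest analyzed sphere."""
        if self.min_volume_mm3 is not None:
            return self.min_volume_mm3
        return 0.1 * sphere_true_volume(min(self.analyzed_diameters))

    @property
    def n_conditions(self) -> int:
        return len(self.fovs_cm) * len(self.kernels) * len(self.thickness_factors)

    def conditions(self):
        for fov in self.fovs_cm:
            for kern in self.kernels:
                for factor in self.thickness_factors:
                    yield fov, kern, int(factor)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernels"] = {k: {"psf_sigma_xy": v.psf_sigma_xy,
                            "noise_sigma": v.noise_sigma}
                        for k, v in self.kernels.items()}
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj
        text = yaml.safe_dump(_clean(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ExperimentConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        if "kernels" in raw:
            raw["kernels"] = {
                name: KernelModel(name=name, **params)
                for name, params in raw["kernels"].items()}
        for key in ("diameters_mm", "fovs_cm", "thickness_factors",
                    "calibration_thresholds", "container_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "calibration_cases" in raw:
            raw["calibration_cases"] = tuple(
                tuple(c) for c in raw["calibration_cases"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """Everything :func:`run_experiment` produced."""

    config: ExperimentConfig
    spec: PhantomSpec
    threshold: float
    calibrations: list[cal.ThresholdCalibration]
    measurements: pd.DataFrame
    results: VolumetryAccuracyResults
    outdir: Path | None = None


# ---------------------------------------------------------------------
# volume synthesis helpers

def _noise_seeds(config: ExperimentConfig) -> dict[tuple[float, str], int]:
    """One sub-2^31 noise seed per (FOV, kernel), derived from config.seed."""
    n = len(config.fovs_cm) * len(config.kernels)
    states = np.random.SeedSequence(config.seed).generate_state(n)
    seeds = {}
    i = 0
    for fov in config.fovs_cm:
        for kern in config.kernels:
            seeds[(fov, kern)] = int(states[i]) & 0x7FFFFFFF
            i += 1
    return seeds


def _crop_to_container(vol: CTVolume, container, margin_voxels: int = 4
                       ) -> CTVolume:
    """Discard the empty air/FOV border around the container footprint."""
    l = vol.pixel_size_xy
    cx, cy, _ = container
    x0 = max(0, math.floor((0.0 - vol.origin[0]) / l) - margin_voxels)
    x1 = min(vol.shape[2], math.ceil((cx - vol.origin[0]) / l) + margin_voxels)
    y0 = max(0, math.floor((0.0 - vol.origin[1]) / l) - margin_voxels)
    y1 = min(vol.shape[1], math.ceil((cy - vol.origin[1]) / l) + margin_voxels)
    return vol.crop(y=slice(y0, y1), x=slice(x0, x1))


class _VolumeFactory:
    """Builds condition volumes, caching per-FOV native voxelizations."""

    def __init__(self, spec: PhantomSpec, config: ExperimentConfig):
        self.spec = spec
        self.config = config
        self.seeds = _noise_seeds(config)
        self._native: dict[float, CTVolume] = {}
        self._noisy: dict[tuple[float, str], CTVolume] = {}

    def native(self, fov: float) -> CTVolume:
        if fov not in self._native:
            t0 = time.perf_counter()
            px = pixel_size(fov, self.config.matrix)
            vol = voxelize(self.spec, px, self.config.native_thickness_mm,
                           supersample=self.config.supersample,
                           matrix=self.config.matrix)
            vol = _crop_to_container(vol, self.config.container_mm)
            vol.provenance["fov_cm"] = fov
            self._native[fov] = vol
            log.info("voxelized FOV %g cm (%s voxels) in %.1f s", fov,
                     "x".join(map(str, vol.shape)), time.perf_counter() - t0)
        return self._native[fov]

    def noisy(self, fov: float, kernel_name: str) -> CTVolume:
        key = (fov, kernel_name)
        if key not in self._noisy:
            # Keep at most one blurred volume cached per FOV.
            self._noisy = {k: v for k, v in self._noisy.items()
                           if k[0] == fov}
            kern = self.config.kernels[kernel_name]
            vol = apply_kernel(self.native(fov), kern, self.seeds[key])
            vol.provenance["kernel"] = kernel_name
            self._noisy[key] = vol
        return self._noisy[key]

    def condition(self, fov: float, kernel_name: str, factor: int) -> CTVolume:
        base = self.noisy(fov, kernel_name)
        if factor == 1:
            return base
        return average_slices(base, SliceAveragingPlan(float(factor)))


# ---------------------------------------------------------------------
# stages

def calibrate_threshold(factory: _VolumeFactory,
                        config: ExperimentConfig
                        ) -> tuple[int, list[cal.ThresholdCalibration]]:
    """Run the per-case threshold sweeps and average the optima."""
    seg = SegmentationParams(
        threshold=0.0, min_volume=config.effective_min_volume(),
        min_neighbors=config.min_neighbors,
        connectivity=config.connectivity,
        neighbor_connectivity=config.neighbor_connectivity)
    calibs = []
    for fov, kern, t_mm in config.calibration_cases:
        factor = int(round(t_mm / config.native_thickness_mm))
        vol = factory.condition(fov, kern, factor)
        points = cal.sweep_thresholds(
            vol, factory.spec, list(config.calibration_thresholds), seg,
            exclude_diameters=config.excluded_diameters)
        opt = cal.optimal_threshold(points)
        case_id = f"{fov:g}cm-{kern}-{t_mm:g}mm"
        calibs.append(cal.ThresholdCalibration(
            case_id=case_id, points=points, optimal_threshold=opt))
        log.info("calibration case %s: optimal threshold %.1f HU",
                 case_id, opt)
    threshold = cal.global_threshold([c.optimal_threshold for c in calibs])
    log.info("global optimal threshold: %d HU", threshold)
    return threshold, calibs


def measure_condition(vol: CTVolume, spec: PhantomSpec,
                      seg: SegmentationParams,
                      condition: dict) -> list[SphereMeasurement]:
    """Segment one condition volume and match components to spheres."""
    labeled = segment(vol, seg)
    comps = measure_components(labeled)
    diag = math.sqrt(2 * vol.pixel_size_xy ** 2 + vol.slice_thickness ** 2)
    return match_to_spheres(comps, spec, voxel_diagonal=diag,
                            condition=condition)


def run_experiment(config: ExperimentConfig,
                   outdir: str | Path | None = None) -> RunResult:
    """Run the full simulate / calibrate / segment / measure / report chain.

    Writes, under ``outdir`` (if given): the phantom manifest, the
    calibration sweep and summary, the tidy per-sphere measurement
    table, slope / precision / error-summary / lookup tables, and a
    ``summary.json`` stamped with the config hash.
    """
    config.validate()
    t_start = time.perf_counter()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    spec = build_phantom_spec(
        layout_seed=config.seed, diameters=list(config.diameters_mm),
        n_replicates=config.n_replicates, container=config.container_mm,
        background_hu=config.background_hu, sphere_hu=config.sphere_hu,
        clearance=config.clearance_mm)
    factory = _VolumeFactory(spec, config)

    calibs: list[cal.ThresholdCalibration] = []
    if config.threshold == "calibrate":
        threshold, calibs = calibrate_threshold(factory, config)
    else:
        threshold = float(config.threshold)

    seg = SegmentationParams(
        threshold=float(threshold),
        min_volume=config.effective_min_volume(),
        min_neighbors=config.min_neighbors,
        connectivity=config.connectivity,
        neighbor_connectivity=config.neighbor_connectivity)

    measurements: list[SphereMeasurement] = []
    for fov, kern, factor in config.conditions():
        t0 = time.perf_counter()
        vol = factory.condition(fov, kern, factor)
        condition = {"fov_cm": fov, "kernel": kern,
                     "slice_thickness_mm": factor * config.native_thickness_mm}
        ms = measure_condition(vol, spec, seg, condition)
        measurements.extend(ms)
        log.info("condition FOV=%g cm kernel=%s t=%g mm: %d/%d detected "
                 "(%.1f s)", fov, kern, condition["slice_thickness_mm"],
                 sum(m.detected for m in ms), len(ms),
                 time.perf_counter() - t0)

    frame = measurements_to_frame(measurements)
    model = VolumetryAccuracyModel(
        frame, exclude_diameters=config.excluded_diameters,
        n_replicates=config.n_replicates)
    results = model.fit()
    log.info("experiment finished in %.1f s", time.perf_counter() - t_start)

    run = RunResult(config=config, spec=spec, threshold=float(threshold),
                    calibrations=calibs, measurements=frame, results=results,
                    outdir=outdir)
    if outdir is not None:
        _write_outputs(run)
    return run


def _write_outputs(run: RunResult) -> None:
    outdir = run.outdir
    assert outdir is not None
    cfg = run.config
    chash = cfg.config_hash()

    cfg.to_yaml(outdir / "config.yaml")
    run.spec.to_json(outdir / "phantom.json")
    run.measurements.to_csv(outdir / "measurements.csv", index=False)
    run.results.slopes.to_csv(outdir / "slopes.csv", index=False)
    run.results.precision.to_csv(outdir / "precision.csv", index=False)
    run.results.error_summaries.to_csv(outdir / "error_summary.csv",
                                       index=False)
    run.results.lookup.to_csv(outdir / "lookup.csv", index=False)

    if run.calibrations:
        rows = []
        for c in run.calibrations:
            for p in c.points:
                rows.append({"case": c.case_id, "threshold_hu": p.threshold,
                             "min_error": p.min_error,
                             "median_error": p.median_error,
                             "max_error": p.max_error, "flag": p.flag})
        pd.DataFrame(rows).to_csv(outdir / "calibration_sweep.csv",
                                  index=False)

    summary = {
        "config_hash": chash,
        "seed": cfg.seed,
        "threshold_hu": run.threshold,
        "calibration_optima_hu": {c.case_id: c.optimal_threshold
                                  for c in run.calibrations},
        "min_volume_mm3": cfg.effective_min_volume(),
        "n_conditions": cfg.n_conditions,
        "n_spheres": len(run.spec.spheres),
        "n_analyzed_per_condition": len(cfg.analyzed_diameters) * cfg.n_replicates,
        "n_measurement_slots": cfg.n_conditions
        * len(cfg.analyzed_diameters) * cfg.n_replicates,
        "slope_range": [float(run.results.slopes["slope"].min()),
                        float(run.results.slopes["slope"].max())],
        "anova_p_values": {k: v.p_value
                           for k, v in run.results.anovas.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "summary.txt").write_text(run.results.summary() + "\n")


# ---------------------------------------------------------------------
# fixtures

def make_fixture(size: str, seed: int, outdir: str | Path | None = None):
    """Build a small deterministic phantom + native volume for testing.

    ``tiny``: three well-separated spheres on a coarse 1 mm grid —
    builds in well under a second.  ``small``: the full 55-sphere
    phantom voxelized at a reduced 128 matrix.  Returns
    ``(spec, volume)`` and optionally writes manifest + NIfTI.
    """
    if size == "tiny":
        spec = build_phantom_spec(
            layout_seed=seed, diameters=[6.35, 9.525, 12.7], n_replicates=1,
            container=(80.0, 80.0, 40.0), clearance=8.0, z_jitter=1.0)
        vol = voxelize(spec, pixel_size_xy=1.0, native_thickness=1.0,
                       supersample=4)
    elif size == "small":
        spec = build_phantom_spec(layout_seed=seed)
        vol = voxelize(spec, pixel_size_xy=pixel_size(20.0, 128),
                       native_thickness=0.625, supersample=4, matrix=128)
        vol = _crop_to_container(vol, CONTAINER_MM)
    else:
        raise ValueError(f"unknown fixture size {size!r}")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spec.to_json(outdir / f"{size}_phantom.json")
        vol.to_nifti(outdir / f"{size}_native.nii.gz")
    return spec, vol
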