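"""Image synthesis: reconstruction-kernel emulation and slice averaging.

A reconstruction kernel trades in-plane sharpness against noise.  It is
emulated as an in-plane Gaussian point-spread function of width
``psf_sigma_xy`` (mm) followed by additive zero-mean Gaussian noise of
``noise_sigma`` (HU).  The defaults order the three clinical kernels as
the study design requires: the standard kernel is the smoothest and
quietest, the lung kernel the sharpest and noisy, bone in between on
sharpness and the noisiest.

Thick slices are synthesized from contiguous thin slices by weighted
averaging: ``slices_per_thick`` thin slices form one thick slice, with
linear interpolation (fractional end weights) when the ratio is not an
integer, and an optional leading ``phase_skip`` consumed first.  The
phase that best matches a reference thick-slice stack is found by
minimizing the mean absolute HU difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "KernelModel", "SliceAveragingPlan", "DEFAULT_KERNELS",
    "apply_kernel", "average_slices", "subtraction_metric",
    "phase_shift_search",
]


@dataclass(frozen=True)
class KernelModel:
    """Reconstruction kernel emulation parameters."""

    name: str
    psf_sigma_xy: float  # mm
    noise_sigma: float   # HU

    def __post_init__(self) -> None:
        if self.psf_sigma_xy < 0 or self.noise_sigma < 0:
            raise ValueError("psf_sigma_xy and noise_sigma must be >= 0")


#: Default kernel models: smoothing standard > bone > lung; noise
#: standard < lung <= bone.
DEFAULT_KERNELS: dict[str, KernelModel] = {
    "standard": KernelModel("standard", psf_sigma_xy=0.8, noise_sigma=4.0),
    "lung": KernelModel("lung", psf_sigma_xy=0.3, noise_sigma=8.0),
    "bone": KernelModel("bone", psf_sigma_xy=0.5, noise_sigma=10.0),
}


@dataclass(frozen=True)
class SliceAveragingPlan:
    """How to collapse thin slices into thick ones.

    ``slices_per_thick`` may be fractional (e.g. 9.625 thin slices per
    5 mm slice when thin-slice spacing is ~0.52 mm); ``phase_skip``
    counts leading thin slices consumed before the first thick slice.
    """

    slices_per_thick: float
    phase_skip: float = 0.0

    def __post_init__(self) -> None:
        if self.slices_per_thick < 1:
            raise ValueError("slices_per_thick must be >= 1")
        if self.phase_skip < 0:
            raise ValueError("phase_skip must be >= 0")


def _noise_variance_factor(sigma_voxels: float) -> float:
    """Per-axis variance retention of a Gaussian filter on white noise."""
    if sigma_voxels <= 0:
        return 1.0
    half = int(4.0 * sigma_voxels + 0.5) + 1
    delta = np.zeros(2 * half + 1)
    delta[half] = 1.0
    w = ndimage.gaussian_filter1d(delta, sigma_voxels)
    return float(np.sum(w * w))


def apply_kernel(volume: CTVolume, kernel: KernelModel,
                 noise_seed: int) -> CTVolume:
    """In-plane Gaussian blur plus seeded additive Gaussian noise.

    The reconstruction kernel shapes noise as well as signal: the added
    noise field is white Gaussian noise filtered in-plane by the same
    PSF and rescaled so its per-voxel standard deviation is
    ``noise_sigma`` HU.  Noise is independent across slices, as it is
    for thin-slice CT.  With ``psf_sigma_xy = 0`` the noise is white.
    """
    data = volume.data.astype(np.float32, copy=True)
    sig = kernel.psf_sigma_xy / volume.pixel_size_xy
    if kernel.psf_sigma_xy > 0:
        data = ndimage.gaussian_filter(data, sigma=(0.0, sig, sig))
    if kernel.noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        noise = rng.standard_normal(data.shape, dtype=np.float32)
        if kernel.psf_sigma_xy > 0:
            noise = ndimage.gaussian_filter(noise, sigma=(0.0, sig, sig))
            noise /= np.float32(_noise_variance_factor(sig))  # back to sd 1
        data += noise * np.float32(kernel.noise_sigma)
    return volume.with_data(
        data, note=f"kernel {kernel.name} psf={kernel.psf_sigma_xy}mm "
                   f"noise={kernel.noise_sigma}HU seed={noise_seed}")


def _group_weights(plan: SliceAveragingPlan, n_thin: int):
    """Yield (first_index, weight_vector) for each output thick slice."""
    spt = plan.slices_per_thick
    start = plan.phase_skip
    eps = 1e-9
    while start + spt <= n_thin + eps:
        end = start + spt
        i0 = int(math.floor(start + eps))
        i1 = int(math.ceil(end - eps))
        i1 = min(i1, n_thin)
        w = np.ones(i1 - i0, dtype=np.float64)
        w[0] = i0 + 1 - start          # fractional coverage of first slice
        w[-1] -= i1 - end              # and of the last
        if len(w) == 1:
            w[0] = end - start
        yield i0, w / spt
        start = end


def average_slices(volume: CTVolume, plan: SliceAveragingPlan) -> CTVolume:
    """Synthesize thick slices as weighted means of thin slices.

    Output slice k is the mean of thin slices covering the interval
    ``[phase_skip + k*spt, phase_skip + (k+1)*spt)`` (thin-slice units),
    boundary slices weighted by fractional coverage.  The output
    thickness is ``slices_per_thick`` times the input thickness.
    """
    n_thin = volume.data.shape[0]
    groups = list(_group_weights(plan, n_thin))
    if not groups:
        raise ValueError(
            f"{n_thin} thin slices cannot form one group of "
            f"{plan.slices_per_thick} after skipping {plan.phase_skip}")
    spt = plan.slices_per_thick
    t_in = volume.slice_thickness

    # Fast path: integer factor, integer phase -> one reshape/mean.
    if (float(spt).is_integer() and float(plan.phase_skip).is_integer()
            and (n_thin - int(plan.phase_skip)) % int(spt) == 0):
        k = int(spt)
        p = int(plan.phase_skip)
        out = volume.data[p:].reshape(-1, k, *volume.data.shape[1:]).mean(
            axis=1, dtype=np.float64).astype(volume.data.dtype)
    else:
        out = np.empty((len(groups), *volume.data.shape[1:]),
                       dtype=volume.data.dtype)
        for k, (i0, w) in enumerate(groups):
            out[k] = np.tensordot(w, volume.data[i0:i0 + len(w)], axes=(0, 0))

    oz = volume.origin[2] + plan.phase_skip * t_in
    return volume.with_data(
        out, slice_thickness=spt * t_in,
        origin=(volume.origin[0], volume.origin[1], oz),
        note=f"average_slices spt={spt} phase_skip={plan.phase_skip}")


def subtraction_metric(a: CTVolume, b: CTVolume) -> float:
    """Mean absolute HU difference between two congruent volumes."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    return float(np.mean(np.abs(a.data.astype(np.float64)
                                - b.data.astype(np.float64))))


def phase_shift_search(
    thin: CTVolume,
    true_thick: CTVolume,
    slices_per_thick: float,
    candidate_skips: list[float] | range = range(0, 10),
) -> SliceAveragingPlan:
    """Find the phase skip aligning averaged thin slices with a thick stack.

    Each candidate ``phase_skip`` is applied, the averaged stack is
    compared against ``true_thick`` over their common leading slices
    with :func:`subtraction_metric`, and the plan with the smallest
    metric wins; ties break toward the smaller skip.
    """
    candidates = sorted(candidate_skips)
    if not candidates:
        raise ValueError("empty candidate phase set")
    best_plan, best_metric = None, math.inf
    for skip in candidates:
        plan = SliceAveragingPlan(slices_per_thick, phase_skip=skip)
        try:
            virt = average_slices(thin, plan)
        except ValueError as exc:
            raise ValueError(
                f"thin stack too short for candidate phase {skip}") from exc
        n = min(virt.data.shape[0], true_thick.data.shape[0])
        if n < 1:
            raise ValueError("no overlapping thick slices to compare")
        metric = float(np.mean(np.abs(
            virt.data[:n].astype(np.float64)
            - true_thick.data[:n].astype(np.float64))))
        if metric < best_metric:
            best_plan, best_metric = plan, metric
    assert best_plan is not None
    return best_plan
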