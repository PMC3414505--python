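"""Ground-truthed multi-subject BOLD cohort simulation.

Every subject of a simulated cohort shares one spatial grid, one activation
mask and one noiseless activation time-course (a boxcar convolved with the
canonical HRF); between-subject anatomical and effect-size variation is
deliberately ignored.  Each voxel of each subject receives an independent
pink-noise draw whose mean-square power is calibrated exactly to
power(signal)/snr, so active voxels contain signal + noise and voxels
outside the mask contain only their noise draw.

Randomness is organised as a seed tree: the master seed spawns one child
stream for activation-mask placement and one per subject, so the noise
realisation of a given subject/voxel does not depend on the SNR level, the
mask, or the number of other subjects' draws.  This makes sweeps over SNR
"matched" by construction: the same seed yields the same noise, only scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignSpec
from .hrf import HRFParams, make_signal
from .noise import pink_noise_matrix, scale_noise_to_snr

__all__ = ["SimulationSpec", "GroundTruthedCohort", "spherical_activation_mask", "simulate_cohort"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated cohort.

    Defaults encode the study conditions: 37 subjects, the 12-block 84-volume
    design at TR 4 s, the lag-6 s/sd-3 s gamma HRF, and a compact synthetic
    activation mask covering ~5% of the grid.  ``snr`` is the signal/noise
    power ratio (study levels 0.01, 0.005, 0.002, 0.001).  Simulated grids
    default to 4 mm isotropic voxels (a scaled-down standard-space sampling).
    """

    grid: tuple[int, int, int] = (30, 30, 30)
    voxel_size: float = 4.0
    n_subjects: int = 37
    design: DesignSpec = field(default_factory=DesignSpec)
    hrf: HRFParams = field(default_factory=HRFParams)
    snr: float = 0.01
    mask_fraction: float = 0.05
    mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid) != 3 or any(int(g) <= 0 for g in self.grid):
            raise ValueError("grid must be three positive dimensions")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction must be in (0, 1]")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != tuple(self.grid):
                raise ValueError("explicit mask must match grid dimensions")
            if not mask.any():
                raise ValueError("activation mask is empty")


@dataclass
class GroundTruthedCohort:
    """Simulated cohort plus the ground truth used to build it."""

    data: np.ndarray  # (n_subjects, X, Y, Z, T)
    mask: np.ndarray  # bool (X, Y, Z) - activation ground truth
    brain_mask: np.ndarray  # bool (X, Y, Z)
    design: DesignSpec
    hrf: HRFParams
    signal: np.ndarray  # (T,) noiseless activation time-course
    voxel_size: float

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[1:4]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def tr(self) -> float:
        return self.design.tr

    def timeseries(self) -> np.ndarray:
        """Data reshaped to (n_subjects, n_voxels, T)."""
        s, x, y, z, t = self.data.shape
        return self.data.reshape(s, x * y * z, t)


def spherical_activation_mask(
    grid: tuple[int, int, int],
    fraction: float,
    seed,
    n_spheres: int = 3,
) -> np.ndarray:
    """Synthetic activation ground truth: a few compact spheres.

    Sphere radius is chosen so that ``n_spheres`` spheres jointly cover about
    ``fraction`` of the grid; centres are placed uniformly at random with the
    whole sphere inside the grid.  Overlap is allowed (the union may cover
    slightly less than ``fraction``), and the result always contains at
    least one voxel.
    """
    grid = tuple(int(g) for g in grid)
    n_total = int(np.prod(grid))
    target = fraction * n_total
    radius = max(1.0, (3.0 * target / (4.0 * np.pi * n_spheres)) ** (1.0 / 3.0))
    rng = np.random.default_rng(seed)
    mask = np.zeros(grid, dtype=bool)
    ii, jj, kk = np.meshgrid(*(np.arange(g) for g in grid), indexing="ij")
    r_int = int(np.ceil(radius))
    for _ in range(n_spheres):
        centre = [
            rng.integers(min(r_int, g // 2), max(g - r_int, g // 2 + 1))
            for g in grid
        ]
        dist2 = (
            (ii - centre[0]) ** 2 + (jj - centre[1]) ** 2 + (kk - centre[2]) ** 2
        )
        mask |= dist2 <= radius**2
    if not mask.any():  # degenerate tiny grids: activate the centre voxel
        mask[tuple(g // 2 for g in grid)] = True
    return mask


def simulate_cohort(spec: SimulationSpec) -> GroundTruthedCohort:
    """Simulate a ground-truthed cohort according to ``spec``.

    Deterministic: identical specs (including seed) produce bit-identical
    cohorts.  The seed tree always reserves its first child stream for mask
    placement, so the noise draws are unchanged when an explicit mask is
    supplied.
    """
    root = np.random.SeedSequence(spec.seed)
    mask_ss, *subject_ss = root.spawn(spec.n_subjects + 1)

    if spec.mask is not None:
        mask = np.asarray(spec.mask, dtype=bool).copy()
    else:
        mask = spherical_activation_mask(spec.grid, spec.mask_fraction, mask_ss)
    if not mask.any():
        raise ValueError("activation mask is empty")

    signal = make_signal(spec.design, spec.hrf)
    n_vox = int(np.prod(spec.grid))
    n_t = spec.design.n_volumes
    mask_flat = mask.ravel()

    data = np.empty((spec.n_subjects, n_vox, n_t), dtype=np.float32)
    for j, ss in enumerate(subject_ss):
        noise = pink_noise_matrix(n_vox, n_t, np.random.default_rng(ss))
        noise = scale_noise_to_snr(signal, noise, spec.snr)
        noise[mask_flat] += signal
        data[j] = noise.astype(np.float32)

    return GroundTruthedCohort(
        data=data.reshape(spec.n_subjects, *spec.grid, n_t),
        mask=mask,
        brain_mask=np.ones(spec.grid, dtype=bool),
        design=spec.design,
        hrf=spec.hrf,
        signal=signal,
        voxel_size=spec.voxel_size,
    )
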