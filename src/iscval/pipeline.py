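"""End-to-end simulation study: simulate -> preprocess -> (GLM || ISC) ->
threshold -> compare against ground truth.

A single master seed drives everything: the cohort generator spawns
per-subject noise streams from it, and the resampling null uses a derived
stream.  Because noise draws do not depend on the SNR parameter, a sweep
over SNR levels with one seed is a matched-noise sweep: the same noise
realisation is rescaled, which removes between-level Monte-Carlo variation
from the Dice-versus-SNR curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GroundTruthedCohort, SimulationSpec, simulate_cohort
from .compare import corr_measure, dice
from .design import DesignSpec, design_events
from .glm import build_design, fit_subject, group_zmap, zmap_pvalues
from .hrf import HRFParams
from .inference import bh_fdr
from .io import write_nifti, write_three_column
from .isc import isc_statistic, pvalues, resample_null
from .preprocess import PreprocParams, highpass, smooth_cohort

__all__ = ["PipelineConfig", "analyze_cohort", "isc_detection", "run_simulation_study"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one simulation study run."""

    grid: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 4.0
    n_subjects: int = 37
    snr_levels: tuple[float, ...] = (0.01, 0.005, 0.002, 0.001)
    mask_fraction: float = 0.05
    design: DesignSpec = field(default_factory=DesignSpec)
    hrf: HRFParams = field(default_factory=HRFParams)
    highpass_cutoff: float = 60.0
    fwhm: float = 5.0
    prewhiten: bool = True
    b: int = 1_000_000
    min_shift: int = 10
    n_sample_voxels: int = 5000
    q_levels: tuple[float, ...] = (0.05, 0.005, 0.001)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["snr_levels"] = list(self.snr_levels)
        d["q_levels"] = list(self.q_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("grid", "snr_levels", "q_levels"):
            if key in d:
                d[key] = tuple(d[key])
        if isinstance(d.get("design"), dict):
            d["design"] = DesignSpec(**d["design"])
        if isinstance(d.get("hrf"), dict):
            d["hrf"] = HRFParams(**d["hrf"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def preproc(self) -> PreprocParams:
        return PreprocParams(
            highpass_cutoff=self.highpass_cutoff,
            fwhm=self.fwhm,
            voxel_size=self.voxel_size,
        )


def analyze_cohort(
    cohort: GroundTruthedCohort, config: PipelineConfig, null_seed
) -> dict:
    """Run both analysis methods on a spatially smoothed cohort.

    ``cohort`` must hold smoothed but not yet high-pass-filtered data: the
    high-pass is applied here so the resampling null can build each
    surrogate by circular-shifting first and filtering after (filtering is
    not shift-invariant, so the order matters for calibration).  Returns
    the ISC statistic map, the pooled resampling null, the group z-map, and
    right-tail p-value maps for both methods, all on the cohort grid.
    """
    ts_raw = cohort.timeseries().astype(float)
    ts = highpass(ts_raw, config.highpass_cutoff, cohort.tr)
    grid = cohort.grid

    # ISC branch
    iscmap = isc_statistic(ts)
    null = resample_null(
        ts_raw,
        b=config.b,
        seed=null_seed,
        n_sample_voxels=config.n_sample_voxels,
        min_shift=config.min_shift,
        highpass_cutoff=config.highpass_cutoff,
        tr=cohort.tr,
    )
    p_isc = pvalues(iscmap, null)

    # GLM branch
    dmat = build_design(
        design_events(cohort.design), cohort.design, cohort.hrf, config.preproc
    )
    betas = np.stack(
        [
            fit_subject(ts[j], dmat, prewhiten=config.prewhiten).beta
            for j in range(cohort.n_subjects)
        ]
    )
    zmap = group_zmap(betas)
    p_glm = zmap_pvalues(zmap)

    return {
        "isc": iscmap.reshape(grid),
        "z": zmap.reshape(grid),
        "p_isc": p_isc.reshape(grid),
        "p_glm": p_glm.reshape(grid),
        "null": null,
    }


def isc_detection(
    cohort: GroundTruthedCohort,
    preproc: PreprocParams,
    q: float,
    b: int,
    null_seed,
    n_sample_voxels: int = 5000,
    min_shift: int = 10,
):
    """ISC-only detection branch: preprocess, test, FDR-threshold.

    Smooths and high-pass filters the cohort, computes the ISC map and its
    circular-shift resampling null (surrogates shifted before filtering),
    and applies BH FDR at level ``q``.  Returns the thresholding result
    (rejections on the cohort grid) and the ISC map.
    """
    smoothed = smooth_cohort(cohort, preproc)
    ts_raw = smoothed.timeseries().astype(float)
    ts = highpass(ts_raw, preproc.highpass_cutoff, cohort.tr)
    iscmap = isc_statistic(ts)
    null = resample_null(
        ts_raw,
        b=b,
        seed=null_seed,
        n_sample_voxels=n_sample_voxels,
        min_shift=min_shift,
        highpass_cutoff=preproc.highpass_cutoff,
        tr=cohort.tr,
    )
    pmap = pvalues(iscmap, null)
    thr = bh_fdr(pmap.reshape(cohort.grid), q)
    return thr, iscmap.reshape(cohort.grid)


def run_simulation_study(
    config: PipelineConfig, out_dir=None
) -> tuple[pd.DataFrame, dict]:
    """Sweep the SNR levels and score both methods against ground truth.

    For every SNR level the cohort is generated, preprocessed, analysed with
    the GLM and the ISC statistic, thresholded with BH FDR at every q level,
    and the Dice index of each detection map against the true activation
    mask is recorded, together with the correlation measure C between |Z|
    and the ISC map.  Deterministic given ``config.seed``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    rows = []
    artifacts: dict = {}
    for level_idx, snr in enumerate(config.snr_levels):
        spec = SimulationSpec(
            grid=config.grid,
            voxel_size=config.voxel_size,
            n_subjects=config.n_subjects,
            design=config.design,
            hrf=config.hrf,
            snr=snr,
            mask_fraction=config.mask_fraction,
            seed=config.seed,
        )
        cohort = simulate_cohort(spec)
        smoothed = smooth_cohort(cohort, config.preproc)
        null_seed = np.random.SeedSequence([config.seed, 1])
        maps = analyze_cohort(smoothed, config, null_seed)
        corr = corr_measure(maps["z"], maps["isc"], mask=cohort.brain_mask)
        level = {"snr": snr, "mask": cohort.mask, **maps, "corr": corr}
        for q in config.q_levels:
            for method, pmap in (("isc", maps["p_isc"]), ("glm", maps["p_glm"])):
                thr = bh_fdr(pmap, q)
                d = (
                    dice(thr.reject, cohort.mask)
                    if thr.n_rejected or cohort.mask.any()
                    else np.nan
                )
                level.setdefault("detections", {})[(q, method)] = thr
                rows.append(
                    {
                        "snr": snr,
                        "q": q,
                        "method": method,
                        "dice_vs_truth": d,
                        "n_detected": thr.n_rejected,
                        "corr_zabs_isc": corr,
                    }
                )
        artifacts[snr] = level
        if out is not None:
            tag = f"snr{snr:g}"
            write_nifti(out / f"{tag}_isc.nii.gz", maps["isc"], config.voxel_size)
            write_nifti(out / f"{tag}_z.nii.gz", maps["z"], config.voxel_size)
            if level_idx == 0:
                write_nifti(
                    out / "truth_mask.nii.gz",
                    cohort.mask.astype(np.uint8),
                    config.voxel_size,
                )
                write_three_column(
                    out / "events.txt", design_events(config.design)
                )

    report = pd.DataFrame(rows)
    if out is not None:
        report.to_csv(out / "report.csv", index=False)
    return report, artifacts
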