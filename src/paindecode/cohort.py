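"""Synthetic two-group fMRI cohort generator.

Produces the inputs the decoding pipeline consumes when no real data are
available: an anatomical region-of-interest mask over a 2 mm MNI-like grid,
per-subject contrast maps (one value per mask voxel) for a chronic-pain
group and a matched control group, optional block-design BOLD time series
from which the first-level GLM can derive those contrasts, and a
demographics table.

The statistical model of a contrast map is

    map = noise_sd * smoothed_white_noise  (+ effect at informative voxels)

where the white noise field is smoothed with a 3D Gaussian kernel (default
FWHM 8 mm, matching common fMRI preprocessing) and rescaled analytically so
the per-voxel standard deviation equals ``noise_sd`` again.  Effects are
expressed in Cohen's d units: the chronic group's mean at an informative
voxel is shifted by ``effect_size * noise_sd``, so a programmed effect of
d = 2 produces a standardized group-mean difference of 2 at that voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "MNI152_2MM_AFFINE", "MaskVolume", "GroundTruth", "BlockDesign",
    "BoldCohort", "make_mask", "default_pain_mask", "default_ground_truth",
    "simulate_contrast_cohort", "simulate_bold_cohort",
    "simulate_demographics", "load_reference_demographics",
]

#: voxel-index -> MNI mm map of the standard 2 mm template grid
MNI152_2MM_AFFINE = np.array([
    [-2.0, 0.0, 0.0, 90.0],
    [0.0, 2.0, 0.0, -126.0],
    [0.0, 0.0, 2.0, -72.0],
    [0.0, 0.0, 0.0, 1.0],
])

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: pain-processing regions of interest: (label, MNI center mm, radius mm).
#: Spheres sized so the default mask holds about 6686 voxels at 2 mm.
DEFAULT_REGIONS = (
    ("S1", (-42.0, -26.0, 58.0), 15.2),
    ("S2", (-50.0, -22.0, 18.0), 14.0),
    ("IPC", (-58.0, -48.0, 26.0), 14.0),
    ("insula", (-38.0, 2.0, 2.0), 13.2),
    ("ACC", (-6.0, 16.0, 34.0), 12.2),
)

#: cluster peaks (MNI mm) and signed effect sizes of the default ground
#: truth: two somatosensory locations where chronic subjects respond less,
#: one inferior-parietal location where they respond more.
DEFAULT_EFFECT_PEAKS = (
    ((-42.0, -25.0, 58.0), -1.0),
    ((-18.0, -43.0, 61.0), -1.0),
    ((-57.0, -49.0, 25.0), +1.0),
)


@dataclass(frozen=True)
class MaskVolume:
    """Analysis voxel set: boolean grid plus voxel->MNI affine.

    ``region_ids`` assigns each included voxel (in C-order of the true grid
    cells) the index of the region it belongs to; ``region_names`` maps
    those indices to labels.  Labels are cosmetic metadata for reporting --
    the decoder never sees them.
    """

    grid: np.ndarray
    affine: np.ndarray
    region_ids: np.ndarray
    region_names: tuple

    def __post_init__(self):
        if self.grid.dtype != bool or self.grid.ndim != 3:
            raise ValueError("grid must be a 3D boolean array")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.n_voxels == 0:
            raise ValueError("mask is empty")
        if self.region_ids.shape != (self.n_voxels,):
            raise ValueError("region_ids must have one entry per mask voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        """(n_voxels, 3) integer grid indices, C-order."""
        return np.argwhere(self.grid)

    @property
    def coords_mm(self) -> np.ndarray:
        """(n_voxels, 3) MNI mm coordinates of the voxel centers."""
        ijk = self.voxel_indices
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def region_label(self, voxel: int) -> str:
        return self.region_names[self.region_ids[voxel]]

    def nearest_voxel(self, mni_mm) -> int:
        """Index (into the mask voxel list) of the voxel nearest a point."""
        d2 = ((self.coords_mm - np.asarray(mni_mm, float)) ** 2).sum(axis=1)
        return int(np.argmin(d2))

    def unmask(self, values, fill=0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a full 3D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError("values must have one entry per mask voxel")
        vol = np.full(self.grid.shape, fill, dtype=float)
        vol[self.grid] = values
        return vol


@dataclass(frozen=True)
class GroundTruth:
    """Programmed group effects of a synthetic cohort.

    informative_indices
        Mask-voxel indices carrying a group effect.
    effect_sizes
        Signed standardized mean differences (Cohen's d): the chronic
        group's mean is shifted by ``d * noise_sd``.  Negative values mean
        chronic < normal (as at the somatosensory voxels); positive values
        mean chronic > normal (inferior parietal).
    noise_sd
        Per-voxel standard deviation of the contrast noise, in contrast
        units (the smoothed field is rescaled to this SD).
    smooth_fwhm
        Full width at half maximum, in mm, of the Gaussian kernel applied
        to the noise field; 0 disables smoothing.
    """

    informative_indices: tuple
    effect_sizes: tuple
    noise_sd: float = 1.0
    smooth_fwhm: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if len(self.informative_indices) != len(self.effect_sizes):
            raise ValueError("one effect size per informative voxel")
        if not np.all(np.isfinite(self.effect_sizes)):
            raise ValueError("effect sizes must be finite")
        if self.noise_sd <= 0 or self.smooth_fwhm < 0:
            raise ValueError("noise_sd must be > 0 and smooth_fwhm >= 0")

    def validate_against(self, mask: MaskVolume) -> None:
        idx = np.asarray(self.informative_indices)
        if idx.size and (idx.min() < 0 or idx.max() >= mask.n_voxels):
            raise ValueError("informative index outside the mask voxel set")

    def to_json(self) -> str:
        return json.dumps({
            "informative_indices": [int(i) for i in self.informative_indices],
            "effect_sizes": [float(d) for d in self.effect_sizes],
            "noise_sd": self.noise_sd,
            "smooth_fwhm": self.smooth_fwhm,
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        d["informative_indices"] = tuple(d["informative_indices"])
        d["effect_sizes"] = tuple(d["effect_sizes"])
        return cls(**d)


@dataclass(frozen=True)
class BlockDesign:
    """Alternating stimulation/rest block paradigm.

    Defaults follow the electrical-stimulation experiment this pipeline
    models: TR 3.67 s, 86 scans per run, two runs, 14 s stimulation
    alternating with 14 s rest repeated 5 times, stimulation first.
    """

    tr: float = 3.67
    n_scans_per_run: int = 86
    n_runs: int = 2
    block_s: float = 14.0
    n_cycles: int = 5
    first_block: str = "stimulation"

    def __post_init__(self):
        if min(self.tr, self.n_scans_per_run, self.n_runs, self.n_cycles) <= 0:
            raise ValueError("design parameters must be positive")
        if self.block_s < 0:
            raise ValueError("block length must be non-negative")
        if self.n_cycles * 2 * self.block_s > self.n_scans_per_run * self.tr:
            raise ValueError("blocks do not fit in the run")
        if self.first_block not in ("stimulation", "rest"):
            raise ValueError("first_block must be 'stimulation' or 'rest'")

    @property
    def n_scans_total(self) -> int:
        return self.n_scans_per_run * self.n_runs

    @property
    def run_duration_s(self) -> float:
        return self.n_scans_per_run * self.tr

    @property
    def stimulation_s_per_run(self) -> float:
        return self.n_cycles * self.block_s


@dataclass
class BoldCohort:
    """Masked BOLD time series for every subject of a synthetic cohort."""

    data: np.ndarray  # (n_subjects, n_voxels, n_scans_total)
    design: BlockDesign
    table: pd.DataFrame
    responsiveness: np.ndarray  # programmed task amplitude per voxel


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------

def make_mask(shape=(91, 109, 91), region_specs=DEFAULT_REGIONS,
              affine=MNI152_2MM_AFFINE) -> MaskVolume:
    """Build a spherical-region mask on a regular grid.

    Parameters
    ----------
    shape : 3 ints
        Grid dimensions.
    region_specs : sequence of (label, center_mm, radius_mm)
        A voxel is included when its center lies within ``radius_mm`` of a
        region center; overlaps resolve to the first-listed region.
    affine : (4, 4) array
        Voxel-index to mm map.

    Raises
    ------
    ValueError
        If any sphere pokes outside the grid or the mask comes out empty.
    """
    affine = np.asarray(affine, dtype=float)
    shape = tuple(int(s) for s in shape)
    inv = np.linalg.inv(affine)
    region_ids_grid = np.full(shape, -1, dtype=np.int16)
    names = []
    idx = np.indices(shape).reshape(3, -1).T
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    for rid, (label, center, radius) in enumerate(region_specs):
        center = np.asarray(center, dtype=float)
        if radius < 0:
            raise ValueError(f"negative radius for region {label!r}")
        # sphere must fit inside the grid
        cv = (inv[:3, :3] @ center + inv[:3, 3])
        rv = radius / np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        if np.any(cv - rv < -0.5) or np.any(cv + rv > np.array(shape) - 0.5):
            raise ValueError(f"region {label!r} does not fit inside the grid")
        inside = ((mm - center) ** 2).sum(axis=1) <= radius ** 2
        inside = inside.reshape(shape)
        new = inside & (region_ids_grid < 0)
        region_ids_grid[new] = rid
        names.append(str(label))
    grid = region_ids_grid >= 0
    if not grid.any():
        raise ValueError("mask is empty: no voxel falls inside any region")
    region_ids = region_ids_grid[grid].astype(np.int16)
    return MaskVolume(grid=grid, affine=affine, region_ids=region_ids,
                      region_names=tuple(names))


def default_pain_mask() -> MaskVolume:
    """Five-region pain-processing mask (~6686 voxels at 2 mm)."""
    return make_mask()


def default_ground_truth(mask: MaskVolume, d: float = 2.0,
                         noise_sd: float = 1.0, smooth_fwhm: float = 8.0,
                         seed: int = 0) -> GroundTruth:
    """Three informative voxels at the canonical cluster peaks.

    Two somatosensory voxels carry effect ``-d`` (chronic < normal) and one
    inferior-parietal voxel carries ``+d`` (chronic > normal).
    """
    idx = []
    eff = []
    for peak, sign in DEFAULT_EFFECT_PEAKS:
        idx.append(mask.nearest_voxel(peak))
        eff.append(sign * d)
    return GroundTruth(informative_indices=tuple(idx),
                       effect_sizes=tuple(eff), noise_sd=noise_sd,
                       smooth_fwhm=smooth_fwhm, seed=seed)


# ---------------------------------------------------------------------------
# noise fields
# ---------------------------------------------------------------------------

def _smoothing_sigma_vox(mask: MaskVolume, fwhm_mm: float) -> np.ndarray:
    return fwhm_mm * _FWHM_TO_SIGMA / mask.voxel_sizes_mm


def _noise_box(mask: MaskVolume, fwhm_mm: float):
    """Bounding box of the mask padded by 4 sigma for edge-free smoothing."""
    ijk = mask.voxel_indices
    sigma = _smoothing_sigma_vox(mask, fwhm_mm)
    pad = np.ceil(4 * sigma).astype(int)
    lo = np.maximum(ijk.min(axis=0) - pad, 0)
    hi = np.minimum(ijk.max(axis=0) + pad + 1, np.array(mask.grid.shape))
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return box, sigma


def _smoothed_unit_noise(rng, box_shape, sigma) -> np.ndarray:
    """White noise smoothed and rescaled back to unit pointwise variance.

    For unit white noise smoothed with a normalized Gaussian kernel the
    output variance is prod_i 1 / (2 sqrt(pi) sigma_i); dividing by its
    square root restores SD 1 without estimating anything from the sample.
    """
    field = rng.standard_normal(box_shape)
    if np.all(sigma <= 0):
        return field
    sd = np.prod(2.0 * np.sqrt(np.pi) * np.maximum(sigma, 1e-12)) ** -0.5
    return gaussian_filter(field, sigma) / sd


def _noise_maps(mask: MaskVolume, truth: GroundTruth, n_maps: int, rng):
    box, sigma = _noise_box(mask, truth.smooth_fwhm)
    grid_box = mask.grid[box]
    out = np.empty((n_maps, mask.n_voxels))
    for s in range(n_maps):
        field = _smoothed_unit_noise(rng, grid_box.shape, sigma)
        out[s] = truth.noise_sd * field[grid_box]
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_contrast_cohort(mask: MaskVolume, truth: GroundTruth,
                             n_per_group: int = 13, seed: int | None = None):
    """Simulate per-subject masked contrast maps for two groups.

    Returns
    -------
    maps : (2 * n_per_group, n_voxels) array
        Row order matches the cohort table: chronic subjects first, then
        normal controls.
    table : pandas.DataFrame
        Demographics with group labels (column ``group``: ``chronic`` /
        ``normal``) and a numeric ``label`` column (chronic = 1).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group for LOOCV")
    truth.validate_against(mask)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = 2 * n_per_group
    maps = _noise_maps(mask, truth, n, rng)
    idx = np.asarray(truth.informative_indices, dtype=np.intp)
    if idx.size:
        shift = np.asarray(truth.effect_sizes) * truth.noise_sd
        maps[:n_per_group, idx] += shift  # chronic rows first
    table = simulate_demographics(n_per_group, rng)
    return maps, table


def simulate_demographics(n_per_group: int, rng) -> pd.DataFrame:
    """Demographics matching the study cohort's marginal distributions.

    Ages uniform 38-65 years, pain thresholds log-normal around 0.7 mA
    (rounded to the 0.1 mA step size of the titration protocol), sex,
    handedness and ethnicity in roughly 9:4, 10:2:1 and 10:3 proportions,
    chronic-pain durations between 0.5 and 5 years.  Only the companion
    statistics consume these; the decoder never sees them.
    """
    def proportioned(choices, weights, k):
        counts = np.floor(np.asarray(weights) / np.sum(weights) * k).astype(int)
        while counts.sum() < k:
            counts[int(np.argmax(weights))] += 1
            weights = np.asarray(weights, float) * [0.9] * len(weights)
        vals = np.repeat(choices, counts)[:k]
        return rng.permutation(vals)

    rows = []
    for group, prefix in (("chronic", "CP"), ("normal", "NC")):
        ages = rng.integers(38, 66, size=n_per_group)
        sexes = proportioned(["F", "M"], [9, 4], n_per_group)
        hands = proportioned(["R", "L", "A"], [10, 2, 1], n_per_group)
        eths = proportioned(["C", "B"], [10, 3], n_per_group)
        thr = np.round(np.clip(
            rng.lognormal(np.log(0.7), 0.35, size=n_per_group), 0.3, 2.0), 1)
        if group == "chronic":
            dur = np.round(rng.uniform(0.5, 5.0, size=n_per_group) * 2) / 2
        else:
            dur = np.full(n_per_group, np.nan)
        for i in range(n_per_group):
            rows.append({
                "subject_id": f"{prefix}{i + 1:02d}",
                "group": group,
                "label": 1 if group == "chronic" else 0,
                "age": int(ages[i]),
                "sex": sexes[i],
                "hand": hands[i],
                "ethnicity": eths[i],
                "threshold_mA": float(thr[i]),
                "duration_years": float(dur[i]),
            })
    return pd.DataFrame(rows)


def simulate_bold_cohort(mask: MaskVolume, truth: GroundTruth,
                         design: BlockDesign | None = None,
                         n_per_group: int = 13, ar_coef: float = 0.3,
                         drift_amplitude: float = 1.0,
                         drift_cutoff_s: float = 128.0,
                         noise_sd: float = 1.0, baseline: float = 100.0,
                         seed: int | None = None) -> BoldCohort:
    """Simulate block-design BOLD series whose GLM contrast equals the
    programmed responsiveness.

    Each voxel's series is ``baseline + responsiveness * (boxcar * HRF) +
    drift + AR(1) noise``; the per-voxel responsiveness maps are drawn from
    the same model as :func:`simulate_contrast_cohort`, so fitting the
    first-level GLM to a noiseless cohort reproduces those maps exactly.
    The drift is a random combination of the run's discrete-cosine
    components slower than ``drift_cutoff_s`` (pointwise SD about
    ``drift_amplitude``), i.e. exactly the scanner-drift band a matched
    high-pass filter removes.
    """
    from . import glm  # local import to avoid a cycle at import time

    design = design or BlockDesign()
    if not -1.0 < ar_coef < 1.0:
        raise ValueError("AR(1) coefficient must lie in (-1, 1)")
    if noise_sd < 0 or drift_amplitude < 0:
        raise ValueError("noise and drift amplitudes must be >= 0")
    truth.validate_against(mask)
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    n = 2 * n_per_group
    resp = _noise_maps(mask, truth, n, rng)
    idx = np.asarray(truth.informative_indices, dtype=np.intp)
    if idx.size:
        resp[:n_per_group, idx] += (
            np.asarray(truth.effect_sizes) * truth.noise_sd)

    regressor = glm.hrf_convolve(glm.build_boxcar(design), design.tr)
    drift_basis = glm.dct_highpass_basis(
        design.n_scans_per_run, design.tr, drift_cutoff_s)[:, 1:]
    nspr = design.n_scans_per_run
    drift_scale = drift_amplitude * np.sqrt(
        nspr / max(drift_basis.shape[1], 1))
    nv = mask.n_voxels
    data = np.empty((n, nv, design.n_scans_total))
    innov_sd = noise_sd * np.sqrt(1.0 - ar_coef ** 2)
    for s in range(n):
        for r in range(design.n_runs):
            sl = slice(r * design.n_scans_per_run,
                       (r + 1) * design.n_scans_per_run)
            run = baseline + resp[s][:, None] * regressor[None, :]
            if drift_amplitude > 0 and drift_basis.shape[1]:
                coef = drift_scale * rng.standard_normal(drift_basis.shape[1])
                run = run + (drift_basis @ coef)[None, :]
            if noise_sd > 0:
                eps = np.empty((nv, design.n_scans_per_run))
                eps[:, 0] = noise_sd * rng.standard_normal(nv)
                innov = innov_sd * rng.standard_normal(
                    (nv, design.n_scans_per_run - 1))
                for t in range(1, design.n_scans_per_run):
                    eps[:, t] = ar_coef * eps[:, t - 1] + innov[:, t - 1]
                run = run + eps
            data[s][:, sl] = run
    table = simulate_demographics(n_per_group, rng)
    return BoldCohort(data=data, design=design, table=table,
                      responsiveness=resp)


def load_reference_demographics() -> pd.DataFrame:
    """Demographics table of the 26-subject chronic low-back-pain cohort.

    Thirteen chronic muscle-skeletal low-back-pain patients and thirteen
    matched controls with age, sex, handedness, ethnicity, electrical pain
    threshold (mA) and, for patients, years since onset.  Used by the
    companion statistics and as the reference for the generator's marginal
    distributions.
    """
    from importlib import resources

    with resources.files("paindecode.data").joinpath(
            "reference_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    df["label"] = (df["group"] == "chronic").astype(int)
    return df
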