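"""Seeded synthetic lesion phantoms for the two-group discrimination study.

No clinical imaging is distributable for this problem, so the package
ships a generator that emulates the statistical structure the analysis
assumes: two groups of masked lesion volumes whose ROI sizes follow the
reported cohort distributions (median 25.31 cm^3 on CT, 9.32 cm^3 on
PET), where the recurrence group differs from the scar group by *local*
texture heterogeneity rather than by any global first-order property.

Every sample is an ellipsoidal ROI inside a small padded grid.  Both
groups share a base texture: a smooth low-frequency bias field plus
homogeneous Gaussian noise, on a lesion-vs-background intensity offset.
Recurrence (LRRC) samples additionally partition the ROI into Voronoi
blobs (Poisson-ish count, default 5-15) and give each blob its own mean
offset, noise-scale multiplier, and one-sided exponential tail-mixture
weight, all scaled by a single ``effect`` parameter.  Between-blob
dispersion makes the local skewness/kurtosis/median/uniformity maps vary
across the ROI, which elevates exactly the dispersion-of-local-statistic
features (S-MAD, K-M90th, U-CV, M-CV, E-IQR, M-IQR).  At ``effect=0``
the blob machinery degenerates to the scar process, so effect-zero
cohorts are genuine null cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import (
    CohortManifest,
    Group,
    ImageVolume,
    ManifestEntry,
    Modality,
    RoiMask,
    write_mask,
    write_volume,
)
from .localmaps import DEFAULT_WINDOW_MM, window_side_pixels

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_sample",
    "generate_samples",
    "generate_cohort",
    "sample_roi_mask",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the clinical cohort the analysis was designed for:
    33 recurrence vs 24 scar lesions; CT grids at (2.0, 0.7, 0.7) mm and
    PET at (3.3, 3.3, 3.3) mm; log-normal ROI volumes with the reported
    medians, clipped to the reported ranges; CT values in a 20-180 HU
    soft-tissue window, PET in a 1-15 SUV window.
    """

    modality: Modality
    n_pos: int = 33
    n_neg: int = 24
    spacing: tuple[float, float, float] = (2.0, 0.7, 0.7)
    volume_median_cm3: float = 25.31
    volume_log_sigma: float = 1.1
    volume_range_cm3: tuple[float, float] = (0.45, 531.43)
    value_window: tuple[float, float] = (20.0, 180.0)
    effect: float = 1.0
    n_blobs: tuple[int, int] = (5, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both group counts must be >= 1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")

    @classmethod
    def ct(cls, **overrides) -> "PhantomConfig":
        return cls(modality=Modality.CT, **overrides)

    @classmethod
    def pet(cls, **overrides) -> "PhantomConfig":
        base = cls(
            modality=Modality.PET,
            spacing=(3.3, 3.3, 3.3),
            volume_median_cm3=9.32,
            volume_range_cm3=(0.98, 189.97),
            value_window=(1.0, 15.0),
        )
        return replace(base, **overrides) if overrides else base


@dataclass
class PhantomSample:
    volume: ImageVolume
    mask: RoiMask
    group: Group
    sample_id: str
    seed: int


# relative amplitudes, as fractions of the value-window width
_SMOOTH_FRAC = 0.18       # low-frequency bias field
_NOISE_FRAC = 0.08        # voxel noise sigma
_BLOB_MEAN_FRAC = 0.04    # between-blob mean offset sigma, per unit effect
_BLOB_LOGSCALE_SD = 0.08  # between-blob log noise-scale sigma, per unit effect
_SKEW_MIN = 0.2           # per-blob skewness magnitude range, per unit effect
_SKEW_MAX = 0.5
_SPIKE_FRAC = (0.004, 0.008)  # per-sample fraction of spike (artifact) voxels
_SPIKE_AMP = 4.0          # spike amplitude floor, in units of the noise sigma
_SMOOTH_SIGMA_MM = 8.0    # correlation length of the bias field
_BACKGROUND_LEVEL = 0.15  # background intensity, fraction of window above lo
_LESION_LEVEL = 0.55      # lesion base intensity, fraction of window above lo


def _ellipsoid_mask(rng: np.random.Generator, config: PhantomConfig) -> np.ndarray:
    """Random ellipsoid whose analytic volume hits a log-normal draw."""
    med = config.volume_median_cm3
    v = med * math.exp(config.volume_log_sigma * rng.standard_normal())
    v = float(np.clip(v, *config.volume_range_cm3))
    u = rng.lognormal(0.0, 0.25, size=2)
    ratios = np.array([u[0], u[1], 1.0 / (u[0] * u[1])])
    r = (3.0 * v * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    semi = r * ratios  # mm, product preserves the target volume
    sp = np.asarray(config.spacing)
    half_px = np.ceil(semi / sp).astype(int)
    wpix = window_side_pixels(
        DEFAULT_WINDOW_MM[config.modality], 0.5 * (sp[1] + sp[2])
    )
    margin = wpix // 2 + 2
    shape = tuple(2 * half_px + 1 + 2 * margin)
    centre = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = (
        ((zz - centre[0]) * sp[0] / semi[0]) ** 2
        + ((yy - centre[1]) * sp[1] / semi[1]) ** 2
        + ((xx - centre[2]) * sp[2] / semi[2]) ** 2
    )
    mask = d2 <= 1.0
    if not mask.any():
        mask[tuple(np.round(centre).astype(int))] = True
    return mask


def sample_roi_mask(config: PhantomConfig, rng: np.random.Generator) -> RoiMask:
    """Draw one ROI mask from the phantom volume law, without texture.

    The volume law (log-normal with the configured median, clipped to the
    configured range, voxelized as a random ellipsoid) is identical to the
    one :func:`generate_sample` uses; this path is for volume-calibration
    studies where only mask geometry matters.
    """
    seed_used = int(rng.integers(0, 2**31 - 1))
    r = np.random.default_rng(seed_used)
    return RoiMask(_ellipsoid_mask(r, config), tuple(config.spacing))


def generate_sample(
    config: PhantomConfig, group: Group, rng: np.random.Generator, sample_id: str = ""
) -> PhantomSample:
    """Draw one masked lesion volume.

    The scar (NO_LRRC) process is spatially homogeneous in its local
    moments; the recurrence (LRRC) process adds effect-scaled between-blob
    dispersion of mean, noise scale, and upper-tail weight.
    """
    group = Group(group)
    seed_used = int(rng.integers(0, 2**31 - 1))
    r = np.random.default_rng(seed_used)

    mask = _ellipsoid_mask(r, config)
    shape = mask.shape
    lo, hi = config.value_window
    width = hi - lo
    sp = np.asarray(config.spacing)

    smooth = r.standard_normal(shape)
    smooth = ndimage.gaussian_filter(smooth, sigma=_SMOOTH_SIGMA_MM / sp)
    s_sd = smooth.std()
    if s_sd > 0:
        smooth *= _SMOOTH_FRAC * width / s_sd

    noise = r.standard_normal(shape)
    sigma = _NOISE_FRAC * width

    base = np.where(mask, lo + _LESION_LEVEL * width, lo + _BACKGROUND_LEVEL * width)
    vox = base + smooth + sigma * noise

    if group is Group.LRRC:
        roi_idx = np.argwhere(mask)
        n_roi = roi_idx.shape[0]
        n_blobs = int(r.integers(config.n_blobs[0], config.n_blobs[1] + 1))
        # keep blobs at least window-sized, or windows average the blob
        # structure away and no local-map dispersion survives
        wpix = window_side_pixels(
            DEFAULT_WINDOW_MM[config.modality], 0.5 * (sp[1] + sp[2])
        )
        # ~spherical blob of in-plane diameter 2*wpix (so typical windows sit
        # inside one blob), corrected for axial voxel anisotropy
        min_blob_vox = max(8, int(4.2 * wpix**3 * 0.5 * (sp[1] + sp[2]) / sp[0]))
        n_blobs = int(np.clip(n_blobs, 1, max(2, n_roi // min_blob_vox)))
        n_blobs = min(n_blobs, n_roi)
        centres = roi_idx[r.choice(n_roi, size=n_blobs, replace=False)]
        # nearest blob centre in physical (mm) metric, one centre at a time
        best = np.full(n_roi, np.inf)
        blob = np.zeros(n_roi, dtype=int)
        for b in range(n_blobs):
            db = (((roi_idx - centres[b]) * sp) ** 2).sum(axis=1)
            closer = db < best
            best[closer] = db[closer]
            blob[closer] = b

        # Every blob mechanism is mean-centred within the sample, so the
        # recurrence group differs by *spatial dispersion* of local
        # statistics, not by sample-level first-order shifts.
        eff = config.effect
        delta = r.normal(0.0, _BLOB_MEAN_FRAC * width * eff, size=n_blobs)
        delta -= delta.mean()
        zlog = r.normal(0.0, 1.0, size=n_blobs)
        scale = np.exp(_BLOB_LOGSCALE_SD * eff * (zlog - zlog.mean()))
        # per-blob target skewness: one-sided within a blob, strength varying
        # between blobs, direction alternating so any lesion mixes regions of
        # mostly-higher with regions of mostly-lower local values
        signs = np.resize((1.0, -1.0), n_blobs)
        gamma_t = eff * signs[r.permutation(n_blobs)] * r.uniform(
            _SKEW_MIN, _SKEW_MAX, size=n_blobs
        )

        zi, yi, xi = roi_idx.T
        for b in range(n_blobs):
            sel = blob == b
            g = gamma_t[b]
            if abs(g) > 1e-9:
                # standardized gamma: mean 0, variance 1, skewness sign(g)*|g|
                k = 4.0 / (g * g)
                draw = np.sign(g) * (r.gamma(k, 1.0, size=int(sel.sum())) - k) / np.sqrt(k)
            else:
                draw = noise[zi[sel], yi[sel], xi[sel]]
            vox[zi[sel], yi[sel], xi[sel]] = (
                base[zi[sel], yi[sel], xi[sel]]
                + smooth[zi[sel], yi[sel], xi[sel]]
                + delta[b]
                + sigma * scale[b] * draw
            )

    # both groups carry sparse signed intensity spikes (reconstruction
    # artifacts / speckle); their per-sample rate varies, so tail-sensitive
    # summaries of any parametric map are noisy in either group
    roi_flat = np.flatnonzero(mask)
    f_spike = r.uniform(*_SPIKE_FRAC)
    n_spike = int(round(f_spike * roi_flat.size))
    if n_spike:
        where = r.choice(roi_flat.size, size=n_spike, replace=False)
        amp = (_SPIKE_AMP + r.exponential(2.0, size=n_spike)) * sigma
        vox.ravel()[roi_flat[where]] += r.choice((-1.0, 1.0), size=n_spike) * amp

    if config.modality is Modality.PET:
        np.clip(vox, 0.01, None, out=vox)
    else:
        np.clip(vox, -1000.0, 3000.0, out=vox)

    volume = ImageVolume(vox, tuple(config.spacing), config.modality)
    return PhantomSample(
        volume=volume,
        mask=RoiMask(mask, tuple(config.spacing)),
        group=group,
        sample_id=sample_id or f"{group.value}_{seed_used}",
        seed=seed_used,
    )


def generate_samples(config: PhantomConfig):
    """Yield the cohort's samples in manifest order (positives first)."""
    rng = np.random.default_rng(config.seed)
    for i in range(config.n_pos):
        yield generate_sample(config, Group.LRRC, rng, sample_id=f"LRRC_{i:03d}")
    for i in range(config.n_neg):
        yield generate_sample(config, Group.NO_LRRC, rng, sample_id=f"NOLRRC_{i:03d}")


def generate_cohort(config: PhantomConfig, outdir) -> CohortManifest:
    """Write a full phantom cohort (NIfTI pairs + manifest CSV) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    provenance = {"config": {**config.__dict__, "modality": config.modality.value}, "samples": {}}
    for sample in generate_samples(config):
        vol_path = outdir / f"{sample.sample_id}_img.nii.gz"
        mask_path = outdir / f"{sample.sample_id}_mask.nii.gz"
        write_volume(sample.volume, vol_path)
        write_mask(sample.mask, mask_path)
        entries.append(
            ManifestEntry(
                sample_id=sample.sample_id,
                modality=config.modality,
                group=sample.group,
                volume_path=str(vol_path),
                mask_path=str(mask_path),
            )
        )
        provenance["samples"][sample.sample_id] = sample.seed
    manifest = CohortManifest(entries)
    manifest.to_csv(outdir / "manifest.csv")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return manifest
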