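import numpy as np
import pytest

from locrad import ImageVolume, Modality, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ct_pair(rng):
    """Single-slice 32x32 CT volume with a centred square ROI."""
    vox = rng.normal(80.0, 15.0, size=(1, 32, 32))
    volume = ImageVolume(vox, (2.0, 1.0, 1.0), Modality.CT)
    support = np.zeros((1, 32, 32), dtype=bool)
    support[0, 8:24, 8:24] = True
    return volume, RoiMask(support, volume.spacing)


@pytest.fixture
def multislice_pair(rng):
    """64x64x8 CT volume with an off-centre box ROI touching no border."""
    vox = rng.normal(100.0, 25.0, size=(8, 64, 64))
    volume = ImageVolume(vox, (2.0, 0.8, 0.8), Modality.CT)
    support = np.zeros((8, 64, 64), dtype=bool)
    support[2:6, 20:44, 12:52] = True
    return volume, RoiMask(support, volume.spacing)


def naive_maps(volume, mask, pixel_side, hist, cv_guard_abs):
    """Brute-force per-voxel double loop over ROI voxels.

    Independent of the vectorised engine's windowing machinery: window
    bounds are recomputed with explicit min/max arithmetic and each
    window is evaluated on its own.
    """
    from locrad._stats import STAT_ORDER, stats_batch

    vox = volume.voxels
    nz, ny, nx = vox.shape
    h = pixel_side // 2
    out = {stat: np.full(vox.shape, np.nan) for stat in STAT_ORDER}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask.support[z, y, x]:
                    continue
                win = vox[
                    z,
                    max(y - h, 0) : min(y + h + 1, ny),
                    max(x - h, 0) : min(x + h + 1, nx),
                ].ravel()
                row = stats_batch(win[None, :], hist, cv_guard_abs=cv_guard_abs)[0]
                for j, stat in enumerate(STAT_ORDER):
                    out[stat][z, y, x] = row[j]
    return out
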