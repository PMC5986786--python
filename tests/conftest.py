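import warnings

import numpy as np
import pytest

from cardiomorph import synthetic as syn
from cardiomorph import outline as om
from cardiomorph.morphometrics import measure_mesh


def make_random_label_grid(rng, shape=(48, 48), n_seeds=14, pixel_size=0.5):
    """Random Voronoi-style label raster (4-connected by construction of
    the repair pass); used as a generic mesh fixture."""
    from cardiomorph.mesh import PixelGrid, repair_label_connectivity

    h, w = shape
    seeds = rng.uniform(0, [w, h], size=(n_seeds, 2))
    yy, xx = np.mgrid[0:h, 0:w]
    d = (xx[..., None] + 0.5 - seeds[:, 0]) ** 2 + (yy[..., None] + 0.5 - seeds[:, 1]) ** 2
    lab = (np.argmin(d, axis=-1) + 1).astype(np.int32)
    lab = repair_label_connectivity(lab)
    return PixelGrid(lab, pixel_size)


def star_polygon(rng, n=12, r_lo=1.0, r_hi=3.0):
    """Random simple (star-convex) polygon."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    rad = rng.uniform(r_lo, r_hi, size=n)
    return np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)


@pytest.fixture(scope="session")
def wt_tissue():
    """One generated wild-type-like heart with its analysis geometry."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = syn.preset("wt-54hpf", seed=1)
        tis = syn.generate_tissue(spec)
        smoothed = om.smooth_outline(tis.traced_outline)
        lm = tis.landmarks
        lms = om.place_landmarks(smoothed, lm["lm1"], lm["lm2"], lm["lm3"], lm["lm4"])
        part = om.partition_segments(smoothed, lms)
        om.assign_cell_regions(tis.mesh, part)
        shapes = measure_mesh(tis.mesh)
        shapes["region"] = [c.region for c in tis.mesh.cells]
    return dict(
        spec=spec,
        tissue=tis,
        smoothed=smoothed,
        landmarks=lms,
        partition=part,
        shapes=shapes,
    )
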