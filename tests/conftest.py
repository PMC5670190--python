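import numpy as np
import pytest

from dropvol.synthetic import (
    HierarchicalDiameterSpec,
    ImageSpec,
    generate_droplet_image,
    generate_hierarchical_diameters,
)


@pytest.fixture(scope="session")
def single_droplet_image():
    """One noiseless 111-um droplet centred in a 400x400 frame at 0.5 um/px."""
    spec = ImageSpec(
        shape=(400, 400), pixel_size_um=0.5, centers_px=[(200.0, 200.0)], diameters_um=[111.0]
    )
    img, truth = generate_droplet_image(spec, seed=1)
    return img, truth, spec


@pytest.fixture(scope="session")
def monolayer_image():
    """A noiseless monolayer of 40 droplets, d ~ N(111, 2) um at 0.5 um/px."""
    spec = ImageSpec(shape=(2200, 2200), pixel_size_um=0.5, n_droplets=40)
    img, truth = generate_droplet_image(spec, seed=7)
    return img, truth, spec


@pytest.fixture(scope="session")
def hierarchical_table():
    """Default study-condition diameter table (6 wells x 3 days x 172 droplets)."""
    return generate_hierarchical_diameters(HierarchicalDiameterSpec(), seed=11)


def match_to_truth(records, truth):
    """Pair accepted droplet records with ground-truth rows by nearest centre."""
    from scipy.spatial import cKDTree

    tree = cKDTree(truth[["center_x_px", "center_y_px"]].to_numpy())
    pairs = []
    for rec in records:
        dist, idx = tree.query(rec.centroid_xy_px)
        pairs.append((rec, truth.iloc[idx], dist))
    return pairs
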