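import numpy as np
import pytest

from rosewater.params import preset


@pytest.fixture(scope="session")
def mb():
    return preset("mb")


@pytest.fixture(scope="session")
def real():
    return preset("real")


@pytest.fixture(scope="session")
def honeycomb():
    from rosewater.lattices import make_honeycomb

    return make_honeycomb(4, bond_length=1.0)


@pytest.fixture(scope="session")
def triangular():
    from rosewater.lattices import make_triangular

    return make_triangular(5, spacing=0.7)


def planted_property_fixture(seed, n_sub=4):
    """Property table with planted states of matter and solid sub-phases.

    Diffusion follows the hierarchy the peeling procedure targets: a
    broad high-valued gas band, two liquid bands of decreasing width
    and a near-zero solid band.  Solid points additionally carry
    ``n_sub`` distinct property signatures.
    Returns (table, truth_labels, state_labels).
    """
    from rosewater.descriptors import FeatureTable, standardize
    from rosewater.observables import OBSERVABLE_NAMES

    rng = np.random.default_rng(seed)
    counts = [150, 150, 150, 440]
    d = np.concatenate([
        rng.uniform(0.5, 3.0, counts[0]),
        np.abs(rng.normal(0.20, 0.05, counts[1])),
        np.abs(rng.normal(0.030, 0.004, counts[2])),
        np.abs(rng.normal(0.0, 2e-4, counts[3])),
    ])
    n = sum(counts)
    state = np.repeat([0, 1, 2, 3], counts)
    raw = rng.normal(0, 0.05, (n, 15))
    centers = rng.normal(0, 2.0, (4, 15))
    for s in range(4):
        raw[state == s] += centers[s]
    solid_idx = np.where(state == 3)[0]
    sub = np.repeat(np.arange(n_sub),
                    len(solid_idx) // n_sub + 1)[:len(solid_idx)]
    sub_centers = rng.normal(0, 3.0, (n_sub, 15))
    for k in range(n_sub):
        raw[solid_idx[sub == k]] += sub_centers[k]
    raw[:, OBSERVABLE_NAMES.index("diffusion")] = d
    pts = [(0.05 + 0.001 * i, 1.0) for i in range(n)]
    table = FeatureTable(pts, standardize(raw), list(OBSERVABLE_NAMES),
                         standardized=True, raw=raw)
    truth = state.copy()
    truth[solid_idx] = 3 + sub
    return table, truth, state


def planted_adf_fixture(seed, n_phases=3, n_points=60):
    """ADF feature table with ``n_phases`` distinct template shapes."""
    from rosewater.descriptors import build_adf_table
    from rosewater.observables import ADF

    rng = np.random.default_rng(seed)
    edges = np.linspace(-60, 60, 76)
    centers = 0.5 * (edges[:-1] + edges[1:])
    templates = [
        np.exp(-centers ** 2 / 30.0),
        np.exp(-(np.abs(centers) - 30.0) ** 2 / 40.0),
        np.ones_like(centers),
        np.exp(-(np.abs(centers) - 50.0) ** 2 / 25.0),
    ]

    pts, adfs_per_point, truth = [], [], []
    for i in range(n_points):
        kind = i % n_phases
        truth.append(kind)
        pts.append((0.05 + 0.005 * i, 1.0))
        adfs = []
        for r in (0.7, 1.0, 1.73, 2.0, 3.0):
            dens = templates[kind] + 0.05 * rng.random(len(centers))
            dens /= dens.sum() * (edges[1] - edges[0])
            adfs.append(ADF(r, 0.05, centers, dens))
        adfs_per_point.append(adfs)
    return build_adf_table(pts, adfs_per_point), np.array(truth)
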