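import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from spinemorph import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def archetypes():
    return synth.default_archetypes()


def make_dataset(seed, n_per_dendrite=50, mixtures=None, n_dendrites=2, **kwargs):
    if mixtures is None:
        mixtures = [(0.25, 0.25, 0.25, 0.25)] * n_dendrites
    specs = [
        synth.DendriteSpec(
            neuron_id="n1",
            dendrite_id=f"d{i}",
            mixture=tuple(mixtures[i]),
            n_spines=n_per_dendrite,
        )
        for i in range(n_dendrites)
    ]
    return synth.sample_dataset(
        synth.SyntheticConfig(dendrites=specs, seed=seed, **kwargs)
    )


@pytest.fixture
def small_dataset():
    return make_dataset(seed=1, n_per_dendrite=10)


def raster_chord_oracle(vertices, point_xy, normal_xy, step=1.0):
    """Independent chord measurement: rasterize the line through the point
    at `step` nm resolution and count the contiguous inside run containing
    the point."""
    poly = Polygon(vertices)
    minx, miny, maxx, maxy = poly.bounds
    reach = float(np.hypot(maxx - minx, maxy - miny)) + 2.0
    n = np.asarray(normal_xy, float)
    n = n / np.linalg.norm(n)
    t = np.arange(-reach, reach + step, step)
    pts = np.asarray(point_xy, float) + t[:, None] * n
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    i0 = int(np.argmin(np.abs(t)))
    if not inside[i0]:
        # point numerically on the boundary: snap to an adjacent inside sample
        near = np.where(inside[max(0, i0 - 2): i0 + 3])[0]
        if len(near) == 0:
            return None
        i0 = max(0, i0 - 2) + int(near[0])
    lo = i0
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(t) - 1 and inside[hi + 1]:
        hi += 1
    return (hi - lo + 1) * step


def ward_bruteforce(X):
    """O(n^3) greedy Ward agglomeration via the Lance-Williams update.

    Returns the merge sequence as a list of (members_a, members_b, height)
    with members as frozensets of observation indices; ties broken by the
    lowest (i, j) cluster-index pair.
    """
    X = np.asarray(X, float)
    n = len(X)
    members = {i: frozenset([i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    active = set(range(n))
    next_id = n
    merges = []
    while len(active) > 1:
        best = min(
            ((d2[(min(i, j), max(i, j))], (min(i, j), max(i, j)))
             for i in active for j in active if i < j),
        )
        dist2, (a, b) = best
        merges.append((members[a], members[b], np.sqrt(dist2)))
        new = next_id
        next_id += 1
        for k in active - {a, b}:
            na, nb, nk = size[a], size[b], size[k]
            dak = d2[(min(a, k), max(a, k))]
            dbk = d2[(min(b, k), max(b, k))]
            dab = d2[(a, b)]
            d2[(k, new)] = ((na + nk) * dak + (nb + nk) * dbk - nk * dab) / (
                na + nb + nk
            )
        members[new] = members[a] | members[b]
        size[new] = size[a] + size[b]
        active -= {a, b}
        active.add(new)
    return merges


def linkage_merge_sequence(Z, n):
    """Decode a scipy linkage matrix into the same merge-sequence format."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for t, row in enumerate(Z):
        a, b, height = int(row[0]), int(row[1]), float(row[2])
        merges.append((members[a], members[b], height))
        members[n + t] = members[a] | members[b]
    return merges
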