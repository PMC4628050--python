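import numpy as np
import pytest

from mammoseg.image_io import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image_factory():
    """Small random images with a fixed seed stream."""

    def make(h=5, w=5, levels=8, seed=0, max_level=255):
        r = np.random.default_rng(seed)
        return GrayImage(
            r.integers(0, levels, size=(h, w)).astype(np.int64), max_level=max_level
        )

    return make


def partition_sets(labels):
    """Canonical partition of a label image as a frozenset of pixel frozensets."""
    labels = np.asarray(labels)
    out = {}
    for idx, lab in enumerate(labels.ravel()):
        out.setdefault(int(lab), set()).add(idx)
    return frozenset(frozenset(s) for s in out.values())


def replay_segmentation_oracle(img, k_scale, connectivity=8):
    """Naive reference for the union-find merge: replay the sorted edge list
    with a dictionary of explicit pixel sets.  Independent of the package's
    RegionForest; used to validate the partition it produces (min_size=1,
    intensity weights)."""
    px = img.pixels
    h, w = px.shape
    edges = []
    for r in range(h):
        for c in range(w):
            i = r * w + c
            neigh = [(r, c + 1), (r + 1, c)]
            if connectivity == 8:
                neigh += [(r + 1, c + 1), (r + 1, c - 1)]
            for rr, cc in neigh:
                if 0 <= rr < h and 0 <= cc < w:
                    j = rr * w + cc
                    a, b = min(i, j), max(i, j)
                    edges.append((float(abs(int(px[r, c]) - int(px[rr, cc]))), a, b))
    edges.sort()
    region_of = {i: i for i in range(h * w)}
    members = {i: {i} for i in range(h * w)}
    internal = {i: 0.0 for i in range(h * w)}
    for wgt, i, j in edges:
        ra, rb = region_of[i], region_of[j]
        if ra == rb:
            continue
        dt = min(internal[ra] + k_scale / len(members[ra]),
                 internal[rb] + k_scale / len(members[rb]))
        if wgt <= dt:
            for p in members[rb]:
                region_of[p] = ra
            members[ra] |= members.pop(rb)
            internal[ra] = max(internal[ra], internal.pop(rb), wgt)
    return frozenset(frozenset(s) for s in members.values())
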