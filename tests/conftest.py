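"""Shared fixtures: random tree builders and hand-made posterior draws."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from softmix.sampler import PosteriorDraws
from softmix.soft_forest import SoftTree, SoftTreeNode, tree_to_arrays

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def random_tree(rng: np.random.Generator, n_vars: int = 3,
                p_split: float = 0.5, max_depth: int = 4,
                tau: float = 0.3) -> SoftTree:
    """Random tree with uniform cutpoints on [0, 1] and N(0,1) leaf values."""

    def build(depth: int) -> SoftTreeNode:
        if depth < max_depth and rng.random() < p_split:
            return SoftTreeNode(split_index=int(rng.integers(n_vars)),
                                cutpoint=float(rng.random()),
                                left=build(depth + 1), right=build(depth + 1))
        return SoftTreeNode(mu=float(rng.standard_normal()))

    root = build(0)
    if root.is_leaf:   # force at least one split so the tree is non-trivial
        root = SoftTreeNode(split_index=0, cutpoint=0.5,
                            left=SoftTreeNode(mu=-1.0),
                            right=SoftTreeNode(mu=1.0))
    return SoftTree(root=root, tau=tau)


def draws_from_forests(forests: list[list[SoftTree]], Zs: np.ndarray,
                       exposure_names=None) -> PosteriorDraws:
    """Wrap explicit forests into a PosteriorDraws with identity scaling.

    Each element of ``forests`` is the list of trees of one retained draw;
    exposures are taken as already lying in [0, 1].
    """
    n, M = Zs.shape
    snapshots = []
    usage = []
    for trees in forests:
        arrs = [tree_to_arrays(t) for t in trees]
        nn = [a["nnode"] for a in arrs]
        off = np.zeros(len(trees) + 1, dtype=np.int64)
        off[1:] = np.cumsum(nn)
        snapshots.append((
            off,
            np.concatenate([a["var"][:k] for a, k in zip(arrs, nn)]),
            np.concatenate([a["cut"][:k] for a, k in zip(arrs, nn)]),
            np.concatenate([a["left"][:k] for a, k in zip(arrs, nn)]),
            np.concatenate([a["right"][:k] for a, k in zip(arrs, nn)]),
            np.concatenate([a["mu"][:k] for a, k in zip(arrs, nn)]),
            np.array([t.tau for t in trees])))
        used = np.zeros(M, dtype=bool)
        for t in trees:
            for b in t.branches():
                used[b.split_index] = True
        usage.append(used)
    D = len(forests)
    return PosteriorDraws(
        beta=np.zeros((D, 0)), sigma2=np.ones(D),
        split_probs=np.full((D, M), 1.0 / M), dirichlet_mass=np.ones(D),
        usage=np.asarray(usage), h_train=np.zeros((D, n)),
        snapshots=snapshots, Zs=Zs, z_min=np.zeros(M), z_range=np.ones(M),
        y_scale=1.0, y_offset=0.0,
        exposure_names=exposure_names or [f"z{m + 1}" for m in range(M)],
        confounder_names=[])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
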