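"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity from the newick string via
dendropy traversals (never through gmbiome's incidence machinery) so that
agreement between the two paths is informative.
"""

import dendropy
import numpy as np
import pandas as pd
import pytest

import gmbiome as g

HAND_TREE = "((A:1,B:0.5):0.5,C:2);"


@pytest.fixture(scope="session")
def hand_tree():
    return g.PhyloTree.from_newick(HAND_TREE)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic cohort under default study conditions."""
    cfg = g.SimConfig(seed=11)
    return cfg, *g.simulate_dataset(cfg)


def fast_config(seed, **overrides):
    """Default study conditions at reduced computational size (fewer taxa,
    shallower libraries) for Monte Carlo loops; effect-size parameters stay
    whatever the caller passes (defaults unless overridden)."""
    base = dict(n_taxa=64, depth_log_mean=float(np.log(8000.0)),
                depth_log_sd=0.25, min_depth=5000)
    base.update(overrides)
    return g.SimConfig(seed=seed, **base)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _dendropy_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def brute_faith_pd(newick: str, taxa, include_root: bool = True) -> float:
    """PD by explicit enumeration of root-ward paths from each present leaf."""
    taxa = list(taxa)
    if not taxa:
        return 0.0
    tree = _dendropy_tree(newick)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    paths = []
    for t in taxa:
        path = set()
        node = leaves[t]
        while node.parent_node is not None:
            path.add(node)
            node = node.parent_node
        paths.append(path)
    spanning = set().union(*paths)
    if not include_root:
        spanning -= set.intersection(*paths)
    return float(sum(nd.edge.length or 0.0 for nd in spanning))


def brute_weighted_unifrac(newick: str, p_a: dict, p_b: dict):
    """Raw and normalized weighted UniFrac by per-branch enumeration of
    descendant leaf sets."""
    tree = _dendropy_tree(newick)
    raw = denom = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        la = sum(p_a.get(t, 0.0) for t in below)
        lb = sum(p_b.get(t, 0.0) for t in below)
        length = node.edge.length or 0.0
        raw += length * abs(la - lb)
        denom += length * (la + lb)
    return raw, (raw / denom if denom > 0 else 0.0)


def brute_windowed_dispersion(D: np.ndarray, f: np.ndarray, w: float):
    """Direct double loop over the definition."""
    n = len(f)
    half = w * (f.max() - f.min())
    out = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        acc = []
        for j in range(n):
            if j != i and abs(f[j] - f[i]) <= half:
                acc.append(D[i, j])
        counts[i] = len(acc)
        if acc:
            out[i] = float(np.mean(acc))
    return out, counts


def random_community(tree: g.PhyloTree, rng, min_taxa=1):
    """A random relative-abundance vector over a random leaf subset."""
    n = tree.n_leaves
    k = int(rng.integers(min_taxa, n + 1))
    chosen = rng.choice(n, size=k, replace=False)
    p = np.zeros(n)
    p[chosen] = rng.dirichlet(np.ones(k))
    return p


def toy_distance(n, rng, ids=None):
    """A random valid distance matrix (symmetric, zero diagonal)."""
    M = rng.random((n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = ids or [f"S{i}" for i in range(n)]
    return g.DistanceMatrix(pd.DataFrame(D, index=ids, columns=ids))
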