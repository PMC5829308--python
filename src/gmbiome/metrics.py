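"""Community-level diversity metrics on OTU count tables.

The analysis unit is an :class:`OtuTable` (samples x OTUs, integer counts).
This module covers the preprocessing the study design calls for — a minimum
read-depth filter, rarefaction to a common depth, a median-of-ratios
size-factor log transform — plus the two phylogenetic metrics at the core of
the analysis, implemented directly on the branch/leaf incidence structure of
:class:`~gmbiome.trees.PhyloTree`:

* Faith's phylogenetic diversity (PD): total branch length of the subtree
  spanning the taxa present in one sample.
* weighted UniFrac: for each branch, the absolute difference in the relative
  abundance it carries in two samples, weighted by branch length; the
  normalized variant divides by the branch-length-weighted abundance sum so
  the distance lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .errors import (
    EmptyResultError,
    FitFailureError,
    InvalidArgumentError,
)
from .trees import PhyloTree

log = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "DistanceMatrix",
    "filter_samples",
    "rarefy",
    "size_factor_transform",
    "faith_pd",
    "faith_pd_series",
    "weighted_unifrac",
    "pairwise_distances",
]


@dataclass
class OtuTable:
    """Samples x OTUs non-negative integer counts with identifiers."""

    counts: pd.DataFrame  # index = sample ids, columns = OTU ids

    def __post_init__(self):
        if self.counts.columns.duplicated().any():
            raise InvalidArgumentError("duplicate OTU ids")
        if self.counts.index.duplicated().any():
            raise InvalidArgumentError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise InvalidArgumentError("counts must be non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    # TSV round trip: rows = samples, header = OTU ids
    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(np.int64))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample ids."""

    values: pd.DataFrame

    def __post_init__(self):
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise InvalidArgumentError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidArgumentError("distance matrix must be symmetric")
        if np.any(~np.isfinite(v)) or np.any(v < -1e-12):
            raise InvalidArgumentError("distances must be finite and non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id",
                           float_format="%.12g")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def filter_samples(table: OtuTable, min_reads: int = 20000) -> OtuTable:
    """Drop samples whose library size falls below ``min_reads`` reads.

    The boundary is inclusive: a sample with exactly ``min_reads`` reads is
    retained. Removed sample ids are logged.
    """
    keep = table.library_sizes >= min_reads
    removed = list(table.sample_ids[~keep])
    if removed:
        log.info("filter_samples: removed %d samples below %d reads: %s",
                 len(removed), min_reads, removed)
    if not keep.any():
        raise EmptyResultError("read-depth filter removed every sample")
    return OtuTable(table.counts.loc[keep])


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample, without replacement, to exactly ``depth`` reads.

    Subsampling a library of counts without replacement is a multivariate
    hypergeometric draw over OTUs; each sample gets an independent draw from
    a generator seeded by ``seed``, so output is reproducible.
    """
    sizes = table.library_sizes.to_numpy()
    if np.any(sizes < depth):
        offenders = list(table.sample_ids[sizes < depth])
        raise InvalidArgumentError(
            f"rarefaction depth {depth} exceeds library size of {offenders}"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return OtuTable(pd.DataFrame(out, index=table.sample_ids, columns=table.otu_ids))


def size_factor_transform(table: OtuTable) -> pd.DataFrame:
    """Median-of-ratios size-factor normalization with a log2 transform.

    Size factor ``s_i`` is the median, over OTUs with strictly positive
    counts in every sample, of ``counts_ij / geomean_j``; the returned matrix
    is ``log2(counts_ij / s_i + 1)``. This stabilizes the count variance
    against library-size differences without discarding reads.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise InvalidArgumentError("size factors need at least 2 samples")
    all_pos = np.all(counts > 0, axis=0)
    if not all_pos.any():
        raise FitFailureError(
            "no OTU has positive counts in every sample; add pseudo-counts "
            "or use rarefaction instead"
        )
    logg = np.log(counts[:, all_pos])
    geomean = logg.mean(axis=0)
    s = np.exp(np.median(logg - geomean, axis=1))
    x = np.log2(counts / s[:, None] + 1.0)
    return pd.DataFrame(x, index=table.sample_ids, columns=table.otu_ids)


def faith_pd(sample_otus, tree: PhyloTree, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of one sample (presence-based).

    Sums branch lengths over the subtree connecting the present taxa to the
    root (``include_root=True``, the default for rooted trees) or to their
    most recent common ancestor (``include_root=False``).
    """
    names = list(sample_otus)
    if not names:
        return 0.0
    idx = tree.leaf_indices(names)
    present = np.zeros(tree.n_leaves, dtype=bool)
    present[idx] = True
    # per-branch count of present descendants (ints: bool matmul saturates)
    below = tree.incidence.astype(np.int64) @ present.astype(np.int64)
    on_path = below > 0
    if not include_root:
        # branches carrying every present taxon lie on the root-to-MRCA path
        on_path &= below < present.sum()
    return float(tree.branch_lengths[on_path].sum())


def faith_pd_series(table: OtuTable, tree: PhyloTree,
                    include_root: bool = True) -> pd.Series:
    """Faith's PD for every sample of a table (vectorized)."""
    idx = tree.leaf_indices(list(table.otu_ids))
    present = np.zeros((len(table.sample_ids), tree.n_leaves), dtype=bool)
    present[:, idx] = table.counts.to_numpy() > 0
    below = tree.incidence.astype(np.int64) @ present.T.astype(np.int64)
    on_path = below > 0
    if not include_root:
        on_path &= below < present.sum(axis=1)[None, :]
    pd_vals = tree.branch_lengths @ on_path
    return pd.Series(pd_vals, index=table.sample_ids, name="faith_pd")


def _branch_loads(p: np.ndarray, tree: PhyloTree, names) -> np.ndarray:
    idx = tree.leaf_indices(list(names))
    full = np.zeros(tree.n_leaves)
    full[idx] = p
    return tree.incidence.astype(float) @ full


def weighted_unifrac(p_a, p_b, tree: PhyloTree, otu_ids,
                     normalized: bool = True) -> float:
    """Weighted UniFrac distance between two relative-abundance vectors.

    raw        = sum_b  l_b * |P_a(b) - P_b(b)|
    normalized = raw / sum_b l_b * (P_a(b) + P_b(b))

    where ``P_x(b)`` is the total relative abundance of leaves below branch
    ``b``. ``p_a``/``p_b`` are aligned with ``otu_ids`` and must be
    non-negative; each should sum to 1 for the usual interpretation.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if np.any(p_a < 0) or np.any(p_b < 0):
        raise InvalidArgumentError("abundances must be non-negative")
    la = _branch_loads(p_a, tree, otu_ids)
    lb = _branch_loads(p_b, tree, otu_ids)
    w = tree.branch_lengths
    raw = float(np.sum(w * np.abs(la - lb)))
    if not normalized:
        return raw
    denom = float(np.sum(w * (la + lb)))
    return raw / denom if denom > 0 else 0.0


def pairwise_distances(table: OtuTable, tree: PhyloTree,
                       normalized: bool = True) -> DistanceMatrix:
    """All-pairs weighted UniFrac over a table's samples.

    One pass computes every sample's per-branch abundance loads; each pairwise
    distance is then a weighted L1 difference of load vectors, so the whole
    matrix costs O(n * branches + n^2 * branches) with small constants.
    """
    rel = table.relative_abundances().to_numpy()
    if np.any(rel.sum(axis=1) <= 0):
        empty = list(table.sample_ids[table.counts.sum(axis=1) == 0])
        raise InvalidArgumentError(f"empty samples have no composition: {empty}")
    idx = tree.leaf_indices(list(table.otu_ids))
    full = np.zeros((rel.shape[0], tree.n_leaves))
    full[:, idx] = rel
    loads = tree.branch_loads(full)  # (n, branches)
    wloads = loads * tree.branch_lengths[None, :]
    n = wloads.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(wloads[i + 1:] - wloads[i]).sum(axis=1)
        d[i, i + 1:] = diff
    d = d + d.T
    if normalized:
        s = wloads.sum(axis=1)
        denom = s[:, None] + s[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, d / denom, 0.0)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(pd.DataFrame(d, index=table.sample_ids,
                                       columns=table.sample_ids))
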