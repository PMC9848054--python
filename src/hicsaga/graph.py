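"""Observed/expected contact graph construction.

Raw binned Hi-C counts decay steeply with genomic distance, so raw
counts mostly encode distance, not compartmental structure. Dividing
each intra-chromosomal count by the mean count at its bin distance
(and each inter-chromosomal count by the global inter mean) removes the
distance effect; the surviving enrichment (O/E > 1) is what the node
embedding should learn from.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse

from .core import BinnedGenome, ContactGraph, RawContacts

MIN_STRATUM_PAIRS = 10  # distance strata smaller than this pool with the next


def filter_bins(
    contacts: RawContacts, genome: BinnedGenome, min_marginal_frac: float = 0.25
) -> np.ndarray:
    """Mask bins with a weak raw contact marginal.

    A bin is masked when its total raw contact count falls below
    ``min_marginal_frac`` times the median marginal of its chromosome.
    Returns a boolean array, True = keep.
    """
    marg = contacts.marginals(genome.n_bins)
    mask = np.ones(genome.n_bins, dtype=bool)
    for ci, (name, _) in enumerate(genome.chromosomes):
        sl = genome.chrom_bins(ci)
        m = marg[sl]
        if m.sum() == 0:
            warnings.warn(f"chromosome {name} has zero total contacts; masking it")
            mask[sl] = False
            continue
        mask[sl] = m >= min_marginal_frac * np.median(m)
    return mask


def _intra_expected(obs: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Distance-stratified expected for one chromosome's dense matrix.

    Mean observed count over unmasked pairs at each bin distance, zeros
    included; strata with fewer than ``MIN_STRATUM_PAIRS`` unmasked
    pairs are pooled with the adjacent longer-distance stratum. Returns
    expected value per distance 1..n-1 (nan where no unmasked pairs).
    """
    n = obs.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for d in range(1, n):
        pair_keep = keep[:-d] & keep[d:]
        counts[d] = int(pair_keep.sum())
        sums[d] = obs[np.arange(n - d), np.arange(d, n)][pair_keep].sum()
    expected = np.full(n, np.nan)
    # pool short strata forward (toward longer distances)
    d = 1
    groups: list[list[int]] = []
    while d < n:
        grp = [d]
        csum = counts[d]
        while csum < MIN_STRATUM_PAIRS and d + 1 < n:
            d += 1
            grp.append(d)
            csum += counts[d]
        groups.append(grp)
        d += 1
    if len(groups) > 1 and counts[groups[-1]].sum() < MIN_STRATUM_PAIRS:
        groups[-2].extend(groups.pop())
    for grp in groups:
        c = counts[grp].sum()
        if c == 0:
            continue
        e = sums[grp].sum() / c
        expected[grp] = e
    return expected


def compute_oe(
    contacts: RawContacts,
    genome: BinnedGenome,
    mask: np.ndarray | None = None,
    edge_threshold: float = 1.0,
) -> ContactGraph:
    """Build the weighted O/E interaction graph.

    Intra-chromosomal expected values are the per-chromosome mean
    observed count at each bin distance (zeros included over unmasked
    pairs); inter-chromosomal expected is the single genome-wide mean
    over unmasked inter pairs. Edges keep weight ``w = observed /
    expected`` when ``w >= edge_threshold`` (``edge_threshold=0`` keeps
    every positive-count pair); the diagonal is excluded.
    """
    n = genome.n_bins
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    mat = sparse.coo_matrix(
        (contacts.count, (contacts.bin1, contacts.bin2)), shape=(n, n)
    ).tocsr()

    edges_i, edges_j, edges_w = [], [], []

    # --- intra-chromosomal, per chromosome
    for ci, (name, _) in enumerate(genome.chromosomes):
        sl = genome.chrom_bins(ci)
        keep = mask[sl]
        if not keep.any():
            continue
        obs = mat[sl, sl].toarray()
        obs = obs + np.triu(obs, 1).T  # symmetric dense view
        nb = obs.shape[0]
        expected = _intra_expected(np.triu(obs), keep)
        iu, ju = np.triu_indices(nb, k=1)
        ok = keep[iu] & keep[ju]
        iu, ju = iu[ok], ju[ok]
        d = ju - iu
        e = expected[d]
        bad = ~np.isfinite(e) | (e <= 0)
        if np.any(bad & (obs[iu, ju] > 0)):
            warnings.warn(
                f"{name}: zero expected in some distance strata; no edges emitted there"
            )
        o = obs[iu, ju]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = o / e
        sel = np.isfinite(w) & (w > 0) & (w >= edge_threshold)
        edges_i.append(iu[sel] + sl.start)
        edges_j.append(ju[sel] + sl.start)
        edges_w.append(w[sel])

    # --- inter-chromosomal, single global expected
    n_keep_per_chrom = np.array(
        [mask[genome.chrom_bins(ci)].sum() for ci in range(len(genome.chromosomes))]
    )
    tot_keep = n_keep_per_chrom.sum()
    n_inter_pairs = (tot_keep**2 - (n_keep_per_chrom**2).sum()) // 2
    inter_sel = (
        (genome.chrom_ids[contacts.bin1] != genome.chrom_ids[contacts.bin2])
        & mask[contacts.bin1]
        & mask[contacts.bin2]
    )
    inter_sum = contacts.count[inter_sel].sum()
    if n_inter_pairs > 0:
        e_inter = inter_sum / n_inter_pairs
        if e_inter > 0:
            b1 = contacts.bin1[inter_sel]
            b2 = contacts.bin2[inter_sel]
            w = contacts.count[inter_sel] / e_inter
            sel = (w > 0) & (w >= edge_threshold)
            edges_i.append(b1[sel])
            edges_j.append(b2[sel])
            edges_w.append(w[sel])
        elif inter_sel.any():
            warnings.warn("zero inter-chromosomal expected; no inter edges emitted")

    if edges_i:
        gi = np.concatenate(edges_i)
        gj = np.concatenate(edges_j)
        w = np.concatenate(edges_w)
    else:
        gi = gj = np.array([], dtype=np.int64)
        w = np.array([])
    nodes = np.unique(np.concatenate([gi, gj]))
    lookup = np.full(n, -1, dtype=np.int64)
    lookup[nodes] = np.arange(nodes.size)
    return ContactGraph(nodes, lookup[gi], lookup[gj], w)


def graph_stats(graph: ContactGraph) -> dict:
    """Read-only diagnostics for logging."""
    if graph.n_edges == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "weight_quantiles": [0.0] * 5,
            "degree_quantiles": [0.0] * 5,
        }
    q = [0, 0.25, 0.5, 0.75, 1.0]
    return {
        "n_nodes": int(graph.n_nodes),
        "n_edges": int(graph.n_edges),
        "weight_quantiles": np.quantile(graph.weight, q).tolist(),
        "degree_quantiles": np.quantile(graph.degree, q).tolist(),
    }
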