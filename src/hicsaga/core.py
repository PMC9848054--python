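"""Shared containers for binned-genome analysis.

Everything downstream (contact graphs, feature matrices, annotations)
lives on one coordinate system: an ordered set of fixed-width bins over
named chromosomes. Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BinnedGenome:
    """Fixed-width binning of a genome.

    Bins tile each chromosome contiguously; the last bin of a chromosome
    may be shorter than ``resolution``. Global bin indices run 0..n-1
    with chromosomes in declaration order.
    """

    chromosomes: tuple[tuple[str, int], ...]
    resolution: int
    chrom_ids: np.ndarray = field(repr=False)  # per-bin chromosome index
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)
    chrom_offsets: np.ndarray = field(repr=False)  # first global bin of each chrom

    @property
    def n_bins(self) -> int:
        return self.starts.size

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chrom_bins(self, ci: int) -> slice:
        """Global-index slice of chromosome ``ci``'s bins."""
        return slice(int(self.chrom_offsets[ci]), int(self.chrom_offsets[ci + 1]))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` on ``chrom``."""
        ci = self.chrom_names.index(chrom)
        length = self.chromosomes[ci][1]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (length {length})")
        return int(self.chrom_offsets[ci]) + pos // self.resolution


def make_binned_genome(
    chrom_sizes: list[tuple[str, int]], resolution: int
) -> BinnedGenome:
    """Tile each chromosome with ``resolution``-bp bins.

    Raises ``ValueError`` on duplicate chromosome names or non-positive
    sizes/resolution.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    names = [n for n, _ in chrom_sizes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    chrom_ids, starts, ends = [], [], []
    offsets = [0]
    for ci, (name, length) in enumerate(chrom_sizes):
        if length <= 0:
            raise ValueError(f"non-positive length for {name}: {length}")
        s = np.arange(0, length, resolution, dtype=np.int64)
        e = np.minimum(s + resolution, length)
        chrom_ids.append(np.full(s.size, ci, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        offsets.append(offsets[-1] + s.size)
    return BinnedGenome(
        chromosomes=tuple((str(n), int(l)) for n, l in chrom_sizes),
        resolution=int(resolution),
        chrom_ids=np.concatenate(chrom_ids),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        chrom_offsets=np.asarray(offsets, dtype=np.int64),
    )


@dataclass
class RawContacts:
    """Symmetric sparse store of binned contact counts.

    Pairs are stored once with ``bin1 <= bin2``; duplicates were summed
    on construction.
    """

    bin1: np.ndarray
    bin2: np.ndarray
    count: np.ndarray

    def __post_init__(self):
        if np.any(self.count < 0):
            raise ValueError("negative contact count")
        if np.any(self.bin1 > self.bin2):
            raise ValueError("pairs must be stored with bin1 <= bin2")

    @classmethod
    def from_triplets(
        cls, bin1: np.ndarray, bin2: np.ndarray, count: np.ndarray
    ) -> "RawContacts":
        """Canonicalize (i<=j) and sum duplicate pairs."""
        b1 = np.minimum(bin1, bin2).astype(np.int64)
        b2 = np.maximum(bin1, bin2).astype(np.int64)
        c = np.asarray(count, dtype=np.float64)
        if c.size and c.min() < 0:
            raise ValueError("negative contact count")
        key = np.stack([b1, b2], axis=1)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        summed = np.zeros(uniq.shape[0])
        np.add.at(summed, inv, c)
        return cls(uniq[:, 0], uniq[:, 1], summed)

    def marginals(self, n_bins: int) -> np.ndarray:
        """Per-bin total raw contact count (diagonal counted once)."""
        m = np.zeros(n_bins)
        np.add.at(m, self.bin1, self.count)
        off = self.bin1 != self.bin2
        np.add.at(m, self.bin2[off], self.count[off])
        return m


@dataclass
class FeatureMatrix:
    """bins x tracks real matrix on a shared binning.

    ``mask`` is True for usable bins; masked-out rows are excluded from
    all downstream statistics. ``nodata`` records, per track, bins with
    no covering data in the source file (value imputed as 0).
    """

    values: np.ndarray
    track_names: list[str]
    mask: np.ndarray
    nodata: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.track_names):
            raise ValueError("track_names length mismatch")
        if self.mask.shape[0] != self.values.shape[0]:
            raise ValueError("mask length mismatch")

    @property
    def n_tracks(self) -> int:
        return self.values.shape[1]

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if other.values.shape[0] != self.values.shape[0]:
            raise ValueError("bin count mismatch")
        return FeatureMatrix(
            np.hstack([self.values, other.values]),
            self.track_names + other.track_names,
            self.mask & other.mask,
        )


MISSING_LABEL = 0  # labels are 1..K; 0 marks unannotated bins


@dataclass
class DomainAnnotation:
    """One domain label per bin, labels in 1..K, 0 = unannotated."""

    labels: np.ndarray
    K: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.size and self.labels.max(initial=0) > self.K:
            raise ValueError("label exceeds K")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")

    @property
    def annotated(self) -> np.ndarray:
        return self.labels != MISSING_LABEL

    @property
    def coverage(self) -> np.ndarray:
        """Fraction of annotated bins per label (sums to 1)."""
        lab = self.labels[self.annotated]
        if lab.size == 0:
            raise ValueError("annotation has no annotated bins")
        counts = np.bincount(lab, minlength=self.K + 1)[1:]
        return counts / lab.size


@dataclass
class LoopSet:
    """Pairs of anchor intervals (chrom, start, end), 0-based half-open."""

    anchor1: list[tuple[str, int, int]]
    anchor2: list[tuple[str, int, int]]

    def __len__(self) -> int:
        return len(self.anchor1)


@dataclass
class GeneTable:
    """Gene intervals with expression (RPKM-like, non-negative)."""

    gene_id: list[str]
    chrom: list[str]
    start: np.ndarray
    end: np.ndarray
    expression: np.ndarray

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.expression = np.asarray(self.expression, dtype=np.float64)
        if np.any(self.expression < 0):
            raise ValueError("negative expression")

    def __len__(self) -> int:
        return len(self.gene_id)


@dataclass
class ContactGraph:
    """Weighted undirected graph over genomic bins.

    Edge weights are observed/expected contact enrichments (> 0, no
    self-loops). ``nodes`` are the global bin indices that carry at
    least one retained edge; ``degree[v]`` is the sum of weights of
    edges incident to node v (indexed like ``nodes``).
    """

    nodes: np.ndarray  # global bin indices, sorted
    edge_i: np.ndarray  # indices into ``nodes``
    edge_j: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        if np.any(self.weight <= 0):
            raise ValueError("edge weights must be positive")
        if np.any(self.edge_i == self.edge_j):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def n_edges(self) -> int:
        return self.weight.size

    @property
    def degree(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        np.add.at(d, self.edge_i, self.weight)
        np.add.at(d, self.edge_j, self.weight)
        return d
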