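"""Readers and writers for the external formats the pipeline touches.

Plain-text formats throughout: sparse contact triplets (with an h5py
fallback for single-resolution cooler HDF5 files), bedGraph / bigWig
signal tracks, BED4 annotations, BEDPE loops, TSV gene and feature
tables, and two-column chrom.sizes. All coordinates are 0-based
half-open.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import (
    BinnedGenome,
    ContactGraph,
    DomainAnnotation,
    FeatureMatrix,
    GeneTable,
    LoopSet,
    RawContacts,
)

# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            out.append((name, int(size)))
    return out


# ---------------------------------------------------------------------------
# contacts


def read_contacts(path, genome: BinnedGenome) -> RawContacts:
    """Load binned contacts from triplet text or a cooler HDF5 file.

    Triplet lines are ``chrom1 start1 chrom2 start2 count`` (whitespace
    separated); coordinates are snapped to bin starts and duplicate
    pairs are summed. Unknown chromosomes and negative counts raise.
    """
    import h5py

    if h5py.is_hdf5(str(path)):
        return _read_cooler(path, genome)
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom1", "start1", "chrom2", "start2", "count"],
        dtype={"chrom1": str, "chrom2": str},
    )
    if (df["count"] < 0).any():
        raise ValueError("negative contact count in triplet file")
    name_to_ci = {n: i for i, n in enumerate(genome.chrom_names)}
    for col in ("chrom1", "chrom2"):
        unknown = set(df[col]) - set(name_to_ci)
        if unknown:
            raise ValueError(f"unknown chromosome(s) in contacts: {sorted(unknown)}")
    res = genome.resolution
    off = genome.chrom_offsets

    def to_bin(chrom_col, start_col):
        ci = df[chrom_col].map(name_to_ci).to_numpy()
        pos = df[start_col].to_numpy(dtype=np.int64)
        lengths = np.array([genome.chromosomes[c][1] for c in ci])
        if np.any(pos < 0) or np.any(pos >= lengths):
            raise ValueError("contact coordinate outside chromosome bounds")
        return off[ci] + pos // res

    b1 = to_bin("chrom1", "start1")
    b2 = to_bin("chrom2", "start2")
    return RawContacts.from_triplets(b1, b2, df["count"].to_numpy(float))


def _read_cooler(path, genome: BinnedGenome) -> RawContacts:
    """Minimal single-resolution cooler (HDF5) reader."""
    import h5py

    with h5py.File(path, "r") as f:
        if "pixels" not in f:
            raise ValueError(
                "HDF5 file lacks a top-level pixels table; "
                "multi-resolution cooler files are not supported"
            )
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c) for c in f["chroms/name"][:]
        ]
        bin_chrom = f["bins/chrom"][:]
        bin_start = f["bins/start"][:].astype(np.int64)
        res = f.attrs.get("bin-size", None)
        if res is not None and int(res) != genome.resolution:
            raise ValueError(
                f"cooler resolution {res} != genome resolution {genome.resolution}"
            )
        name_to_ci = {n: i for i, n in enumerate(genome.chrom_names)}
        unknown = set(np.take(chrom_names, np.unique(bin_chrom))) - set(name_to_ci)
        if unknown:
            raise ValueError(f"unknown chromosome(s) in cooler: {sorted(unknown)}")
        ci = np.array([name_to_ci[chrom_names[c]] for c in bin_chrom])
        global_id = genome.chrom_offsets[ci] + bin_start // genome.resolution
        b1 = global_id[f["pixels/bin1_id"][:]]
        b2 = global_id[f["pixels/bin2_id"][:]]
        cnt = f["pixels/count"][:].astype(np.float64)
    return RawContacts.from_triplets(b1, b2, cnt)


def write_contacts(contacts: RawContacts, genome: BinnedGenome, path) -> None:
    """Write contacts as triplet text (inverse of the text reader)."""
    names = genome.chrom_names
    with open(path, "w") as fh:
        for i, j, c in zip(contacts.bin1, contacts.bin2, contacts.count):
            fh.write(
                f"{names[genome.chrom_ids[i]]}\t{genome.starts[i]}\t"
                f"{names[genome.chrom_ids[j]]}\t{genome.starts[j]}\t{c:g}\n"
            )


# ---------------------------------------------------------------------------
# 1D signal tracks


def _bin_intervals(
    chroms, starts, ends, values, genome: BinnedGenome, aggregation: str
):
    """Coverage-weighted binning of intervals; uncovered bases count as 0."""
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"aggregation must be 'mean' or 'sum', got {aggregation!r}")
    n = genome.n_bins
    total = np.zeros(n)  # sum of value * covered-length
    covered = np.zeros(n)  # covered bases per bin
    name_to_ci = {nm: i for i, nm in enumerate(genome.chrom_names)}
    res = genome.resolution

    last_end: dict[str, tuple[int, int]] = {}  # chrom -> (end, line no.)
    for ln, (chrom, s, e, v) in enumerate(zip(chroms, starts, ends, values), 1):
        if chrom not in name_to_ci:
            raise ValueError(f"unknown chromosome {chrom!r} (line {ln})")
        if e <= s:
            raise ValueError(f"empty/negative interval at line {ln}")
        if chrom in last_end and s < last_end[chrom][0]:
            raise ValueError(
                f"unsorted or overlapping bedGraph interval at line {ln} "
                f"(previous interval on {chrom} ends at {last_end[chrom][0]})"
            )
        last_end[chrom] = (e, ln)
        ci = name_to_ci[chrom]
        length = genome.chromosomes[ci][1]
        if e > length:
            raise ValueError(f"interval beyond {chrom} end at line {ln}")
        off = int(genome.chrom_offsets[ci])
        b0 = off + s // res
        b1 = off + (e - 1) // res
        if b0 == b1:
            total[b0] += v * (e - s)
            covered[b0] += e - s
        else:
            for b in range(b0, b1 + 1):
                bs = genome.starts[b]
                be = genome.ends[b]
                ov = min(e, be) - max(s, bs)
                total[b] += v * ov
                covered[b] += ov
    widths = (genome.ends - genome.starts).astype(float)
    if aggregation == "mean":
        col = total / widths
    else:
        col = total
    nodata = covered == 0
    return col, nodata


def read_signal_track(
    path, genome: BinnedGenome, aggregation: str = "mean", name: str | None = None
) -> FeatureMatrix:
    """Bin one bedGraph or bigWig track onto the genome.

    ``mean`` aggregation is a coverage-weighted average with uncovered
    bases counted as value 0; ``sum`` conserves value x length mass.
    Bins with no covering data get 0 and a no-data flag.
    """
    spath = str(path)
    if spath.endswith((".bw", ".bigwig", ".bigWig")):
        col, nodata = _read_bigwig(spath, genome, aggregation)
    else:
        try:
            df = pd.read_csv(
                spath,
                sep=r"\s+",
                header=None,
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
                comment="#",
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        if df.empty:
            col = np.zeros(genome.n_bins)
            nodata = np.ones(genome.n_bins, dtype=bool)
        else:
            col, nodata = _bin_intervals(
                df["chrom"],
                df["start"].to_numpy(np.int64),
                df["end"].to_numpy(np.int64),
                df["value"].to_numpy(float),
                genome,
                aggregation,
            )
    track = name or str(path)
    fm = FeatureMatrix(
        col[:, None], [track], np.ones(genome.n_bins, dtype=bool), nodata[:, None]
    )
    return fm


def _read_bigwig(path: str, genome: BinnedGenome, aggregation: str):
    import pyBigWig  # optional backend

    col = np.zeros(genome.n_bins)
    nodata = np.ones(genome.n_bins, dtype=bool)
    with pyBigWig.open(path) as bw:
        for ci, (name, length) in enumerate(genome.chromosomes):
            if name not in bw.chroms():
                continue
            sl = genome.chrom_bins(ci)
            nb = sl.stop - sl.start
            mean = bw.stats(name, 0, length, type="mean", nBins=nb, exact=True)
            cov = bw.stats(name, 0, length, type="coverage", nBins=nb, exact=True)
            mean = np.array([0.0 if m is None else m for m in mean])
            cov = np.array([0.0 if c is None else c for c in cov])
            widths = (genome.ends[sl] - genome.starts[sl]).astype(float)
            vals = mean * cov  # zero-filled mean over the whole bin
            col[sl] = vals if aggregation == "mean" else vals * widths
            nodata[sl] = cov == 0
    return col, nodata


def stack_signal_tracks(tracks: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-stack single-track matrices; mask bins with no data in
    at least half the tracks (conservative genome-wide mask)."""
    values = np.hstack([t.values for t in tracks])
    names = sum((t.track_names for t in tracks), [])
    nodata = np.hstack([t.nodata for t in tracks])
    # no data in >= half the tracks -> bin masked genome-wide
    mask = nodata.sum(axis=1) * 2 < len(tracks)
    return FeatureMatrix(values, names, mask, nodata)


# ---------------------------------------------------------------------------
# loops / genes


def read_loops(path, genome: BinnedGenome) -> LoopSet:
    """Read BEDPE (6+ columns): chrom1 start1 end1 chrom2 start2 end2."""
    a1, a2 = [], []
    sizes = dict(genome.chromosomes)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"malformed BEDPE line {ln}: need >= 6 columns")
            c1, s1, e1, c2, s2, e2 = parts[:6]
            for c, s, e in ((c1, s1, e1), (c2, s2, e2)):
                if c not in sizes:
                    raise ValueError(f"unknown chromosome {c!r} at BEDPE line {ln}")
                if not 0 <= int(s) < int(e) <= sizes[c]:
                    raise ValueError(f"anchor outside chromosome bounds, line {ln}")
            a1.append((c1, int(s1), int(e1)))
            a2.append((c2, int(s2), int(e2)))
    return LoopSet(a1, a2)


def write_loops(loops: LoopSet, path) -> None:
    with open(path, "w") as fh:
        for (c1, s1, e1), (c2, s2, e2) in zip(loops.anchor1, loops.anchor2):
            fh.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\n")


def read_genes(path) -> GeneTable:
    """TSV with columns gene_id, chrom, start, end, expression (RPKM)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end"]
    if not all(c in df.columns for c in required):
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["gene_id", "chrom", "start", "end", "expression"],
        )
    expr_col = "expression" if "expression" in df.columns else df.columns[4]
    return GeneTable(
        df["gene_id"].astype(str).tolist(),
        df["chrom"].astype(str).tolist(),
        df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64),
        df[expr_col].to_numpy(float),
    )


def write_genes(genes: GeneTable, path) -> None:
    pd.DataFrame(
        {
            "gene_id": genes.gene_id,
            "chrom": genes.chrom,
            "start": genes.start,
            "end": genes.end,
            "expression": genes.expression,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations (BED4, run-length merged)


def write_annotation(annotation: DomainAnnotation, genome: BinnedGenome, path) -> None:
    """Write BED4 with the label in column 4 as ``label_k``; runs of
    adjacent equal-label bins merge into one record."""
    labels = annotation.labels
    names = genome.chrom_names
    with open(path, "w") as fh:
        for ci in range(len(genome.chromosomes)):
            sl = genome.chrom_bins(ci)
            lab = labels[sl]
            starts = genome.starts[sl]
            ends = genome.ends[sl]
            run_start = 0
            for b in range(1, lab.size + 1):
                if b == lab.size or lab[b] != lab[run_start]:
                    if lab[run_start] != 0:
                        fh.write(
                            f"{names[ci]}\t{starts[run_start]}\t{ends[b - 1]}\t"
                            f"label_{lab[run_start]}\n"
                        )
                    run_start = b


def read_annotation(path, genome: BinnedGenome, K: int | None = None) -> DomainAnnotation:
    """Inverse of :func:`write_annotation` on per-bin labels."""
    labels = np.zeros(genome.n_bins, dtype=np.int32)
    name_to_ci = {n: i for i, n in enumerate(genome.chrom_names)}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"BED line {ln}: label column missing")
            chrom, s, e, label = parts[:4]
            if chrom not in name_to_ci:
                raise ValueError(f"unknown chromosome {chrom!r} at line {ln}")
            k = int(label.removeprefix("label_"))
            ci = name_to_ci[chrom]
            off = int(genome.chrom_offsets[ci])
            b0 = off + int(s) // genome.resolution
            b1 = off + (int(e) - 1) // genome.resolution
            labels[b0 : b1 + 1] = k
    kmax = K if K is not None else int(labels.max(initial=1))
    return DomainAnnotation(labels, kmax)


# ---------------------------------------------------------------------------
# feature matrices and graphs as TSV / edge-list text


def write_features(features: FeatureMatrix, genome: BinnedGenome, path) -> None:
    names = genome.chrom_names
    df = pd.DataFrame(
        {
            "chrom": [names[c] for c in genome.chrom_ids],
            "start": genome.starts,
            "end": genome.ends,
        }
    )
    for t, nm in enumerate(features.track_names):
        df[nm] = features.values[:, t]
    df["_mask"] = features.mask.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_features(path, genome: BinnedGenome) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] != genome.n_bins:
        raise ValueError("feature table row count does not match genome bins")
    track_names = [c for c in df.columns if c not in ("chrom", "start", "end", "_mask")]
    mask = (
        df["_mask"].to_numpy(bool)
        if "_mask" in df.columns
        else np.ones(genome.n_bins, dtype=bool)
    )
    return FeatureMatrix(df[track_names].to_numpy(float), track_names, mask)


def write_graph(graph: ContactGraph, path) -> None:
    """Edge-list text ``i j w`` in global bin indices."""
    with open(path, "w") as fh:
        for a, b, w in zip(graph.edge_i, graph.edge_j, graph.weight):
            fh.write(f"{graph.nodes[a]}\t{graph.nodes[b]}\t{w:.17g}\n")


def read_graph(path) -> ContactGraph:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["i", "j", "w"])
    gi = df["i"].to_numpy(np.int64)
    gj = df["j"].to_numpy(np.int64)
    nodes = np.unique(np.concatenate([gi, gj]))
    lookup = {int(g): k for k, g in enumerate(nodes)}
    ei = np.array([lookup[int(g)] for g in gi], dtype=np.int64)
    ej = np.array([lookup[int(g)] for g in gj], dtype=np.int64)
    return ContactGraph(nodes, ei, ej, df["w"].to_numpy(float))
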