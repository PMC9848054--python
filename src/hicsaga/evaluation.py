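"""Annotation evaluation statistics.

Implements the variance-explained (VE) family — generic per-bin VE,
gene-expression VE with majority-label gene assignment and an inverse
hyperbolic sine transform, and multi-phase replication-timing VE — plus
the ChIA-PET loop observed/expected enrichment score, block/i.i.d.
bootstrap standard errors, and annotation-overlap measures (fold-change
matrix and adjusted Rand index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from .core import BinnedGenome, DomainAnnotation, GeneTable, LoopSet

DEFAULT_BLOCK_BINS = 10  # 1 Mb at 100 kb


# ---------------------------------------------------------------------------
# variance explained


@dataclass
class VeResult:
    ve: float
    per_label_means: dict[int, float]
    n_used: int
    bootstrap_se: float | None = None
    per_phase: list[float] | None = None


def _ve_core(labels: np.ndarray, signal: np.ndarray) -> tuple[float, dict[int, float]]:
    """VE = 1 - sum(d_i^2) / sum((s_i - s̄)^2) where d is the residual
    of predicting each position by its label's mean signal."""
    if labels.size < 2:
        raise ValueError("need at least 2 usable positions")
    sbar = signal.mean()
    ss_tot = np.sum((signal - sbar) ** 2)
    if ss_tot == 0:
        raise ValueError("signal has zero variance; VE undefined")
    mus: dict[int, float] = {}
    pred = np.empty_like(signal)
    for k in np.unique(labels):
        sel = labels == k
        mu = signal[sel].mean()
        mus[int(k)] = float(mu)
        pred[sel] = mu
    ss_res = np.sum((signal - pred) ** 2)
    return float(1.0 - ss_res / ss_tot), mus


def variance_explained(
    annotation: DomainAnnotation, signal: np.ndarray, signal_mask: np.ndarray | None = None
) -> VeResult:
    """Fraction of per-bin signal variance explained by the annotation.

    Bins missing either the annotation or the signal are excluded.
    Bounded in [0, 1]: the label-mean predictor can never do worse than
    the global mean on the same data.
    """
    signal = np.asarray(signal, dtype=float)
    use = annotation.annotated & np.isfinite(signal)
    if signal_mask is not None:
        use &= np.asarray(signal_mask, dtype=bool)
    ve, mus = _ve_core(annotation.labels[use], signal[use])
    return VeResult(ve, mus, int(use.sum()))


def assign_gene_labels(
    annotation: DomainAnnotation, genes: GeneTable, genome: BinnedGenome
) -> tuple[np.ndarray, np.ndarray]:
    """Majority annotated-bin label over each gene's interval.

    Ties go to the lowest label index; genes overlapping only
    unannotated bins are dropped. Returns (gene indices kept, labels).
    """
    name_to_ci = {n: i for i, n in enumerate(genome.chrom_names)}
    res = genome.resolution
    kept, glabels = [], []
    for g in range(len(genes)):
        chrom = genes.chrom[g]
        if chrom not in name_to_ci:
            continue
        ci = name_to_ci[chrom]
        off = int(genome.chrom_offsets[ci])
        nchrom = genome.chrom_bins(ci).stop - off
        b0 = max(genes.start[g] // res, 0)
        b1 = min((genes.end[g] - 1) // res, nchrom - 1)
        if b1 < b0:
            continue
        lab = annotation.labels[off + b0 : off + b1 + 1]
        lab = lab[lab != 0]
        if lab.size == 0:
            continue
        counts = np.bincount(lab)
        kept.append(g)
        glabels.append(int(np.argmax(counts)))  # argmax -> lowest index on ties
    return np.asarray(kept, dtype=int), np.asarray(glabels, dtype=np.int32)


def gene_expression_ve(
    annotation: DomainAnnotation, genes: GeneTable, genome: BinnedGenome
) -> VeResult:
    """VE of asinh-transformed expression over genes (not bins)."""
    kept, glabels = assign_gene_labels(annotation, genes, genome)
    if kept.size == 0:
        raise ValueError("no genes overlap annotated bins")
    expr = np.arcsinh(genes.expression[kept])
    ve, mus = _ve_core(glabels, expr)
    return VeResult(ve, mus, int(kept.size))


def coarsen_phases(
    rt_fine: np.ndarray, fine_resolution: int, genome: BinnedGenome
) -> np.ndarray:
    """Average fine-resolution phase tracks into genome bins, then
    renormalize each bin's phase vector to sum 1 (zero-mass bins stay
    zero). ``rt_fine`` is (n_fine_bins x n_phases), fine bins tiling the
    same chromosomes in order."""
    if genome.resolution % fine_resolution != 0:
        raise ValueError("fine resolution must divide the working resolution")
    n_phases = rt_fine.shape[1]
    out = np.zeros((genome.n_bins, n_phases))
    fine_row = 0
    for ci, (_, length) in enumerate(genome.chromosomes):
        n_fine = -(-length // fine_resolution)
        block = rt_fine[fine_row : fine_row + n_fine]
        fine_row += n_fine
        sl = genome.chrom_bins(ci)
        per_bin = genome.resolution // fine_resolution
        for b in range(sl.stop - sl.start):
            seg = block[b * per_bin : (b + 1) * per_bin]
            if seg.size:
                out[sl.start + b] = seg.mean(axis=0)
    if fine_row != rt_fine.shape[0]:
        raise ValueError("fine track length does not match genome")
    total = out.sum(axis=1, keepdims=True)
    nz = total[:, 0] > 0
    out[nz] /= total[nz]
    return out


def replication_timing_ve(
    annotation: DomainAnnotation,
    rt_fine: np.ndarray,
    fine_resolution: int,
    genome: BinnedGenome,
    n_phases: int = 6,
) -> VeResult:
    """Mean VE across replication-timing phases at working resolution.

    Fine (e.g. 1 kb) phase proportions are averaged into working bins
    and renormalized; bins with zero phase mass are excluded. Phases
    that coarsen to a constant track are skipped with a warning.
    """
    if rt_fine.shape[1] != n_phases:
        raise ValueError(f"expected {n_phases} phases, got {rt_fine.shape[1]}")
    coarse = coarsen_phases(rt_fine, fine_resolution, genome)
    has_mass = coarse.sum(axis=1) > 0
    per_phase = []
    mus_all: dict[int, float] = {}
    n_used = 0
    for p in range(n_phases):
        try:
            r = variance_explained(annotation, coarse[:, p], signal_mask=has_mass)
        except ValueError:
            warnings.warn(f"phase {p + 1} is degenerate (constant); excluded from RT VE")
            per_phase.append(float("nan"))
            continue
        per_phase.append(r.ve)
        n_used = r.n_used
    defined = [v for v in per_phase if np.isfinite(v)]
    if not defined:
        raise ValueError("no replication-timing phase has a defined VE")
    return VeResult(float(np.mean(defined)), mus_all, n_used, per_phase=per_phase)


# ---------------------------------------------------------------------------
# loop enrichment


@dataclass
class LoopEnrichment:
    observed: np.ndarray  # K x K, upper-triangular storage (i <= j)
    expected: np.ndarray
    oe_score: float
    total: int
    n_dropped: int


def _anchor_bin(anchor: tuple[str, int, int], genome: BinnedGenome) -> int:
    chrom, s, e = anchor
    mid = (s + e) // 2
    return genome.bin_index(chrom, min(mid, dict(genome.chromosomes)[chrom] - 1))


def loop_enrichment(
    annotation: DomainAnnotation, loops: LoopSet, genome: BinnedGenome
) -> LoopEnrichment:
    """Observed/expected enrichment of same-label loops.

    Each anchor maps to the bin containing its midpoint; loops with an
    unannotated anchor are dropped (counted). With label coverages C,
    the expected count carries E_ii = totalO*Ci^2 on the diagonal and
    2*totalO*Ci*Cj on unordered pairs i<j, so sum(E) = totalO exactly.
    The score is sum_i(O_ii) / sum_i(E_ii).
    """
    K = annotation.K
    O = np.zeros((K, K))
    dropped = 0
    for a1, a2 in zip(loops.anchor1, loops.anchor2):
        b1 = _anchor_bin(a1, genome)
        b2 = _anchor_bin(a2, genome)
        l1 = int(annotation.labels[b1])
        l2 = int(annotation.labels[b2])
        if l1 == 0 or l2 == 0:
            dropped += 1
            continue
        i, j = min(l1, l2) - 1, max(l1, l2) - 1
        O[i, j] += 1
    total = int(O.sum())
    if total == 0:
        raise ValueError("no usable loops (all dropped or empty input)")
    C = annotation.coverage
    E = 2 * total * np.outer(C, C)
    E = np.triu(E, 1) + np.diag(total * C**2)
    diag_e = np.trace(E)
    score = float(np.trace(O) / diag_e) if diag_e > 0 else float("nan")
    return LoopEnrichment(O, E, score, total, dropped)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_se(
    statistic,
    n_units: int,
    n_reps: int,
    seed: int = 0,
    block: int | None = None,
) -> float:
    """SE of a statistic under resampling of its exchangeable units.

    ``statistic(idx)`` must evaluate the statistic on the resampled
    unit indices ``idx``. Per-bin statistics should pass ``block`` (in
    bins; blocks of contiguous bins are resampled with replacement to
    the original length); gene/loop statistics resample units i.i.d.
    Raises if the statistic is undefined in more than 20% of
    replicates. SE uses denominator n_reps - 1.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_reps):
        if block is None:
            idx = rng.integers(0, n_units, size=n_units)
        else:
            n_blocks = -(-n_units // block)
            starts = rng.integers(0, max(n_units - block, 0) + 1, size=n_blocks)
            idx = np.concatenate([np.arange(s, s + block) for s in starts])[:n_units]
        try:
            values.append(float(statistic(idx)))
        except (ValueError, ZeroDivisionError):
            failures += 1
    if failures > 0.2 * n_reps:
        raise ValueError(f"statistic undefined in {failures}/{n_reps} replicates")
    return float(np.std(values, ddof=1))


def ve_bootstrap_se(
    annotation: DomainAnnotation,
    signal: np.ndarray,
    n_reps: int = 100,
    block_bins: int = DEFAULT_BLOCK_BINS,
    seed: int = 0,
) -> float:
    """Block-bootstrap SE of per-bin VE (label/signal pairs resampled
    together in contiguous blocks)."""
    signal = np.asarray(signal, dtype=float)
    use = annotation.annotated & np.isfinite(signal)
    lab = annotation.labels[use]
    sig = signal[use]

    def stat(idx):
        return _ve_core(lab[idx], sig[idx])[0]

    return bootstrap_se(stat, lab.size, n_reps, seed=seed, block=block_bins)


def oe_bootstrap_se(
    annotation: DomainAnnotation,
    loops: LoopSet,
    genome: BinnedGenome,
    n_reps: int = 100,
    seed: int = 0,
) -> float:
    """i.i.d. loop-resampling SE of the loop OE score."""
    def stat(idx):
        sub = LoopSet(
            [loops.anchor1[i] for i in idx], [loops.anchor2[i] for i in idx]
        )
        return loop_enrichment(annotation, sub, genome).oe_score

    return bootstrap_se(stat, len(loops), n_reps, seed=seed)


# ---------------------------------------------------------------------------
# annotation overlap


@dataclass
class OverlapResult:
    fold_change: np.ndarray  # K_a x K_b
    ari: float
    n_bins: int


def overlap(annotation_a: DomainAnnotation, annotation_b: DomainAnnotation) -> OverlapResult:
    """Fold-change overlap matrix and adjusted Rand index over bins
    annotated in both: fc[a,b] = P(a,b) / (P(a) P(b))."""
    both = annotation_a.annotated & annotation_b.annotated
    if not both.any():
        raise ValueError("annotations share no annotated bins")
    la = annotation_a.labels[both]
    lb = annotation_b.labels[both]
    n = la.size
    Ka, Kb = annotation_a.K, annotation_b.K
    joint = np.zeros((Ka, Kb))
    np.add.at(joint, (la - 1, lb - 1), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = joint / np.outer(pa, pb)
    fc[~np.isfinite(fc)] = 0.0
    return OverlapResult(fc, float(adjusted_rand_score(la, lb)), n)


def expression_t_tests(
    annotation: DomainAnnotation, genes: GeneTable, genome: BinnedGenome
) -> dict[tuple[int, int], float]:
    """Welch two-sample t-test p-values on asinh-transformed expression
    between every pair of gene label groups (descriptive; uncorrected)."""
    kept, glabels = assign_gene_labels(annotation, genes, genome)
    expr = np.arcsinh(genes.expression[kept])
    out = {}
    labels = np.unique(glabels)
    for a in range(labels.size):
        for b in range(a + 1, labels.size):
            xa = expr[glabels == labels[a]]
            xb = expr[glabels == labels[b]]
            if xa.size >= 2 and xb.size >= 2:
                out[(int(labels[a]), int(labels[b]))] = float(
                    sps.ttest_ind(xa, xb, equal_var=False).pvalue
                )
    return out


# ---------------------------------------------------------------------------
# aggregate report


def domain_lengths(annotation: DomainAnnotation, genome: BinnedGenome) -> np.ndarray:
    """Lengths (bp) of runs of constant labels; unannotated bins and
    chromosome boundaries break runs."""
    lengths = []
    for ci in range(len(genome.chromosomes)):
        sl = genome.chrom_bins(ci)
        lab = annotation.labels[sl]
        widths = genome.ends[sl] - genome.starts[sl]
        run_start = 0
        for b in range(1, lab.size + 1):
            if b == lab.size or lab[b] != lab[run_start]:
                if lab[run_start] != 0:
                    lengths.append(int(widths[run_start:b].sum()))
                run_start = b
    return np.asarray(lengths, dtype=np.int64)


def evaluate_all(
    annotation: DomainAnnotation,
    genome: BinnedGenome,
    signals: np.ndarray | None = None,
    signal_names: list[str] | None = None,
    genes: GeneTable | None = None,
    rt_fine: np.ndarray | None = None,
    rt_fine_resolution: int | None = None,
    loops: dict[str, LoopSet] | None = None,
) -> dict:
    """Every applicable statistic, JSON-serializable; missing inputs
    are skipped with a note."""
    report: dict = {"K": annotation.K, "coverage": annotation.coverage.tolist()}
    lens = domain_lengths(annotation, genome)
    report["domain_lengths_bp"] = {
        "n": int(lens.size),
        "mean": float(lens.mean()) if lens.size else 0.0,
        "quartiles": np.percentile(lens, [25, 50, 75]).tolist() if lens.size else [],
    }
    notes = []
    if signals is not None:
        names = signal_names or [f"track_{t + 1}" for t in range(signals.shape[1])]
        report["signal_ve"] = {
            nm: variance_explained(annotation, signals[:, t]).ve
            for t, nm in enumerate(names)
        }
    else:
        notes.append("no signals provided")
    if genes is not None:
        r = gene_expression_ve(annotation, genes, genome)
        report["gene_expression_ve"] = r.ve
        report["gene_expression_n"] = r.n_used
    else:
        notes.append("no genes provided")
    if rt_fine is not None:
        r = replication_timing_ve(
            annotation, rt_fine, rt_fine_resolution, genome, n_phases=rt_fine.shape[1]
        )
        report["rt_ve"] = r.ve
        report["rt_ve_per_phase"] = r.per_phase
    else:
        notes.append("no replication timing provided")
    if loops:
        report["loop_oe"] = {}
        for nm, ls in loops.items():
            e = loop_enrichment(annotation, ls, genome)
            report["loop_oe"][nm] = {
                "oe_score": e.oe_score,
                "total_loops": e.total,
                "dropped": e.n_dropped,
            }
    else:
        notes.append("no loops provided")
    report["notes"] = notes
    return report
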