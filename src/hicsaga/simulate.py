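"""Synthetic genomes with planted factorized domain structure.

The generator operationalizes the premise that 1D functional state and
3D structural (compartmental) state are distinct organizational layers:
every bin carries a combined state that factors into a functional state
(visible only in the 1D signal tracks) and a structural state (visible
only in the Hi-C contact affinities). Gene expression varies by the
combined state and loops prefer anchors in the same structural state,
so each evaluation statistic has a planted effect size to detect.

Default scale — 2 chromosomes x 500 bins at 100 kb (100 Mb), 3
functional x 2 structural states — is small enough for routine test
runs while leaving enough bins for recovery of the planted states.

All generators are bit-reproducible under a fixed seed; contact counts
are Poisson (no overdispersion knob in this version).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinnedGenome, FeatureMatrix, GeneTable, LoopSet, RawContacts, make_binned_genome

DEFAULT_RESOLUTION = 100_000
DEFAULT_BINS_PER_CHROM = 500
DEFAULT_N_CHROMS = 2
DEFAULT_F_STATES = 3
DEFAULT_S_STATES = 2
DEFAULT_STICKINESS = 0.9
DEFAULT_DECAY = 1.0
DEFAULT_DEPTH = 60.0
DEFAULT_INTER_SCALE = 0.01
DEFAULT_AFFINITY_WITHIN = 3.0
DEFAULT_AFFINITY_BETWEEN = 1.0
DEFAULT_N_TRACKS = 12
DEFAULT_MEAN_SEPARATION = 1.0
DEFAULT_NOISE_SD = 0.6
DEFAULT_N_GENES = 400
DEFAULT_N_LOOPS = 2000
DEFAULT_SAME_STATE_FRACTION = 0.9


@dataclass
class SyntheticTruth:
    """Planted per-bin states; the combined state determines both
    factors (combined = functional * S + structural)."""

    genome: BinnedGenome
    functional_states: np.ndarray
    structural_states: np.ndarray
    combined_states: np.ndarray
    n_functional: int
    n_structural: int
    config: dict = field(default_factory=dict)

    @property
    def n_combined(self) -> int:
        return self.n_functional * self.n_structural


def default_genome(
    n_chroms: int = DEFAULT_N_CHROMS,
    bins_per_chrom: int = DEFAULT_BINS_PER_CHROM,
    resolution: int = DEFAULT_RESOLUTION,
) -> BinnedGenome:
    sizes = [(f"chr{c + 1}", bins_per_chrom * resolution) for c in range(n_chroms)]
    return make_binned_genome(sizes, resolution)


def plant_states(
    genome: BinnedGenome,
    n_functional: int = DEFAULT_F_STATES,
    n_structural: int = DEFAULT_S_STATES,
    stickiness: float = DEFAULT_STICKINESS,
    seed: int = 0,
) -> SyntheticTruth:
    """Per-chromosome sticky Markov chain over combined states.

    Self-transition probability is ``stickiness``; the rest of the mass
    spreads uniformly, giving geometric runs with expected length
    1/(1 - stickiness) bins.
    """
    if not 0 < stickiness < 1:
        raise ValueError("stickiness must be in (0, 1)")
    K = n_functional * n_structural
    if K > genome.n_bins:
        raise ValueError("more combined states than bins")
    rng = np.random.default_rng(seed)
    combined = np.empty(genome.n_bins, dtype=np.int32)
    for ci in range(len(genome.chromosomes)):
        sl = genome.chrom_bins(ci)
        n = sl.stop - sl.start
        path = np.empty(n, dtype=np.int32)
        path[0] = rng.integers(K)
        for b in range(1, n):
            if rng.random() < stickiness or K == 1:
                path[b] = path[b - 1]
            else:
                step = rng.integers(K - 1)
                path[b] = step if step < path[b - 1] else step + 1
        combined[sl] = path
    return SyntheticTruth(
        genome=genome,
        functional_states=combined // n_structural,
        structural_states=combined % n_structural,
        combined_states=combined,
        n_functional=n_functional,
        n_structural=n_structural,
        config={
            "stickiness": stickiness,
            "seed": seed,
            "n_functional": n_functional,
            "n_structural": n_structural,
        },
    )


def default_affinity(
    n_structural: int,
    within: float = DEFAULT_AFFINITY_WITHIN,
    between: float = DEFAULT_AFFINITY_BETWEEN,
) -> np.ndarray:
    return np.full((n_structural, n_structural), between) + np.eye(n_structural) * (
        within - between
    )


def simulate_contacts(
    truth: SyntheticTruth,
    decay_exponent: float = DEFAULT_DECAY,
    affinity: np.ndarray | None = None,
    depth: float = DEFAULT_DEPTH,
    inter_scale: float = DEFAULT_INTER_SCALE,
    seed: int = 0,
) -> RawContacts:
    """Poisson contact counts with power-law distance decay modulated
    by structural-state affinity.

    Intra-pair rate: depth * |i-j|^(-decay) * affinity[s_i, s_j];
    inter-pair rate: depth * inter_scale * affinity[s_i, s_j].
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if affinity is None:
        affinity = default_affinity(truth.n_structural)
    affinity = np.asarray(affinity, dtype=float)
    if np.any(affinity <= 0):
        raise ValueError("affinity entries must be positive")
    genome = truth.genome
    s = truth.structural_states
    rng = np.random.default_rng(seed)
    n = genome.n_bins
    iu, ju = np.triu_indices(n, k=1)
    same_chrom = genome.chrom_ids[iu] == genome.chrom_ids[ju]
    aff = affinity[s[iu], s[ju]]
    lam = np.where(
        same_chrom,
        depth * np.abs(ju - iu, dtype=float) ** (-decay_exponent) * aff,
        depth * inter_scale * aff,
    )
    counts = rng.poisson(lam).astype(np.float64)
    nz = counts > 0
    return RawContacts(iu[nz].astype(np.int64), ju[nz].astype(np.int64), counts[nz])


def simulate_signals(
    truth: SyntheticTruth,
    n_tracks: int = DEFAULT_N_TRACKS,
    mean_separation: float = DEFAULT_MEAN_SEPARATION,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> FeatureMatrix:
    """Non-negative signal tracks keyed to the functional states only.

    Per (functional state, track) latent means are drawn once from
    N(0, mean_separation^2); emissions are exponentiated Gaussians
    (lognormal-shaped, like coverage tracks), so the structural factor
    is invisible in 1D.
    """
    rng = np.random.default_rng(seed)
    state_means = rng.normal(0.0, mean_separation, (truth.n_functional, n_tracks))
    f = truth.functional_states
    latent = state_means[f] + rng.normal(0.0, noise_sd, (truth.genome.n_bins, n_tracks))
    values = np.exp(latent)
    names = [f"signal_{t + 1}" for t in range(n_tracks)]
    return FeatureMatrix(values, names, np.ones(truth.genome.n_bins, dtype=bool))


def simulate_genes(
    truth: SyntheticTruth,
    n_genes: int = DEFAULT_N_GENES,
    expr_means: np.ndarray | None = None,
    dispersion: float = 0.5,
    seed: int = 0,
) -> GeneTable:
    """Genes placed uniformly with lognormal lengths (median 30 kb);
    expression is lognormal around the mean of the combined state at
    the gene midpoint. ``expr_means`` is indexed by combined state (log
    scale); the default spreads states over e^0 .. e^2 RPKM-like units.
    """
    rng = np.random.default_rng(seed)
    K = truth.n_combined
    if expr_means is None:
        expr_means = np.linspace(2.0, 0.0, K)
    expr_means = np.asarray(expr_means, dtype=float)
    if expr_means.size != K:
        raise ValueError("expr_means must have one entry per combined state")
    genome = truth.genome
    names = genome.chrom_names
    gene_id, chroms = [], []
    starts = np.empty(n_genes, dtype=np.int64)
    ends = np.empty(n_genes, dtype=np.int64)
    expr = np.empty(n_genes)
    chrom_lengths = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
    p = chrom_lengths / chrom_lengths.sum()
    for g in range(n_genes):
        ci = rng.choice(len(names), p=p)
        length = int(np.exp(rng.normal(np.log(30_000), dispersion)))
        length = max(length, 200)
        start = int(rng.integers(0, max(chrom_lengths[ci] - length, 1)))
        end = min(start + length, int(chrom_lengths[ci]))
        mid_bin = genome.bin_index(names[ci], (start + end) // 2)
        state = truth.combined_states[mid_bin]
        expr[g] = np.exp(rng.normal(expr_means[state], dispersion))
        gene_id.append(f"gene_{g + 1}")
        chroms.append(names[ci])
        starts[g] = start
        ends[g] = end
    return GeneTable(gene_id, chroms, starts, ends, expr)


def simulate_loops(
    truth: SyntheticTruth,
    n_loops: int = DEFAULT_N_LOOPS,
    same_state_fraction: float = DEFAULT_SAME_STATE_FRACTION,
    seed: int = 0,
    anchor_halfwidth: int = 500,
) -> LoopSet:
    """Loops whose anchors prefer the same structural state.

    With probability ``same_state_fraction`` the second anchor is drawn
    from bins sharing the first anchor's structural state; otherwise
    both anchors are independent uniform bins.
    """
    if not 0 <= same_state_fraction <= 1:
        raise ValueError("same_state_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genome = truth.genome
    names = genome.chrom_names
    s = truth.structural_states
    bins_by_state = [np.flatnonzero(s == k) for k in range(truth.n_structural)]

    def anchor_for(b: int) -> tuple[str, int, int]:
        chrom = names[genome.chrom_ids[b]]
        mid = int((genome.starts[b] + genome.ends[b]) // 2)
        length = dict(genome.chromosomes)[chrom]
        lo = max(mid - anchor_halfwidth, 0)
        hi = min(mid + anchor_halfwidth, length)
        return (chrom, lo, hi)

    a1, a2 = [], []
    for _ in range(n_loops):
        b1 = int(rng.integers(genome.n_bins))
        if rng.random() < same_state_fraction:
            pool = bins_by_state[s[b1]]
            b2 = int(pool[rng.integers(pool.size)])
        else:
            b2 = int(rng.integers(genome.n_bins))
        a1.append(anchor_for(b1))
        a2.append(anchor_for(b2))
    return LoopSet(a1, a2)


def simulate_rt(
    truth: SyntheticTruth,
    fine_resolution: int = 1000,
    n_phases: int = 6,
    concentration: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """Six-phase replication-timing proportions at fine resolution.

    Each combined state gets a characteristic phase profile (active
    states replicate early); fine bins draw Dirichlet proportions
    around their bin's state profile. Returns (n_fine_bins x n_phases).
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome
    K = truth.n_combined
    # state k peaks at phase proportional to its rank (early -> late)
    peaks = np.linspace(0, n_phases - 1, K)
    profiles = np.empty((K, n_phases))
    for k in range(K):
        d = np.arange(n_phases) - peaks[k]
        profiles[k] = np.exp(-0.5 * d**2)
        profiles[k] /= profiles[k].sum()
    per_bin = genome.resolution // fine_resolution
    rows = []
    for ci in range(len(genome.chromosomes)):
        sl = genome.chrom_bins(ci)
        for b in range(sl.start, sl.stop):
            prof = profiles[truth.combined_states[b]]
            n_fine = max((genome.ends[b] - genome.starts[b]) // fine_resolution, 1)
            rows.append(rng.dirichlet(concentration * prof, size=n_fine))
    return np.vstack(rows)


@dataclass
class SyntheticDataset:
    truth: SyntheticTruth
    contacts: RawContacts
    signals: FeatureMatrix
    genes: GeneTable
    loops: LoopSet
    rt_fine: np.ndarray
    rt_fine_resolution: int


def simulate_dataset(
    seed: int = 0,
    genome: BinnedGenome | None = None,
    n_functional: int = DEFAULT_F_STATES,
    n_structural: int = DEFAULT_S_STATES,
    stickiness: float = DEFAULT_STICKINESS,
    depth: float = DEFAULT_DEPTH,
    affinity: np.ndarray | None = None,
    n_tracks: int = DEFAULT_N_TRACKS,
    mean_separation: float = DEFAULT_MEAN_SEPARATION,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_genes: int = DEFAULT_N_GENES,
    n_loops: int = DEFAULT_N_LOOPS,
    same_state_fraction: float = DEFAULT_SAME_STATE_FRACTION,
    with_rt: bool = True,
) -> SyntheticDataset:
    """One coherent dataset; sub-generator seeds derive from ``seed``."""
    if genome is None:
        genome = default_genome()
    ss = np.random.SeedSequence(seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    truth = plant_states(genome, n_functional, n_structural, stickiness, seed=sub[0])
    contacts = simulate_contacts(truth, affinity=affinity, depth=depth, seed=sub[1])
    signals = simulate_signals(
        truth, n_tracks, mean_separation=mean_separation, noise_sd=noise_sd, seed=sub[2]
    )
    genes = simulate_genes(truth, n_genes, seed=sub[3])
    loops = simulate_loops(truth, n_loops, same_state_fraction, seed=sub[4])
    rt = simulate_rt(truth, seed=sub[5]) if with_rt else np.zeros((0, 6))
    return SyntheticDataset(truth, contacts, signals, genes, loops, rt, 1000)
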