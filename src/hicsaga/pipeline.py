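"""End-to-end wiring: contacts -> O/E graph -> embedding -> HMM annotation.

Kept separate from the CLI so the full workflow is callable (and
testable) as a library function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinnedGenome, ContactGraph, DomainAnnotation, FeatureMatrix, RawContacts
from .embedding import EmbeddingModel, TrainConfig, export_features, train
from .graph import compute_oe, filter_bins, graph_stats
from .hmm import SagaModel, annotate


@dataclass
class PipelineResult:
    genome: BinnedGenome
    bin_mask: np.ndarray
    graph: ContactGraph
    embedding: EmbeddingModel
    structural: FeatureMatrix
    functional: FeatureMatrix
    annotations: dict[str, DomainAnnotation] = field(default_factory=dict)
    models: dict[str, SagaModel] = field(default_factory=dict)
    graph_summary: dict = field(default_factory=dict)


def run_pipeline(
    genome: BinnedGenome,
    contacts: RawContacts,
    signals: FeatureMatrix,
    K: int,
    seed: int = 0,
    modes: tuple[str, ...] = ("combined",),
    train_config: TrainConfig | None = None,
    edge_threshold: float = 1.0,
    min_marginal_frac: float = 0.25,
) -> PipelineResult:
    """Run graph construction, embedding, and annotation in the
    requested modes ('functional', 'structural', 'combined').

    One shared bin mask — contact-marginal filter AND signal no-data
    mask AND graph membership — keeps every matrix aligned, so the
    three annotation modes are fit on exactly the same bins.
    """
    bin_mask = filter_bins(contacts, genome, min_marginal_frac) & signals.mask
    graph = compute_oe(contacts, genome, bin_mask, edge_threshold=edge_threshold)
    cfg = train_config or TrainConfig(seed=seed)
    model = train(graph, cfg)
    structural = export_features(model, genome, bin_mask)
    common = structural.mask & bin_mask
    functional = FeatureMatrix(signals.values, list(signals.track_names), common.copy())
    structural = FeatureMatrix(structural.values, list(structural.track_names), common.copy())
    result = PipelineResult(
        genome=genome,
        bin_mask=common,
        graph=graph,
        embedding=model,
        structural=structural,
        functional=functional,
        graph_summary=graph_stats(graph),
    )
    for mode in modes:
        if mode == "combined":
            ann, m = annotate(functional, structural, genome, K, seed=seed)
        elif mode == "functional":
            ann, m = annotate(functional, None, genome, K, seed=seed)
        elif mode == "structural":
            ann, m = annotate(None, structural, genome, K, seed=seed)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        result.annotations[mode] = ann
        result.models[mode] = m
    return result
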