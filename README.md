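# hicsaga

Integrative chromatin domain annotation from Hi-C and 1D functional
genomic signals.

## The problem

Chromatin domains can be seen through two windows: 1D functional assays
(ChIP-seq histone marks, DNase-seq) describe local biochemical activity,
while Hi-C contact maps describe 3D compartmentalization — which regions
of the genome co-locate in the nucleus. The two layers are correlated
but not redundant: loop-scale structure and replication timing follow
the structural layer, gene expression follows the functional layer.
Segmentation-and-genome-annotation (SAGA) models such as ChromHMM or
Segway consume only 1D tracks, and integrative extensions that bolt
Hi-C onto them (graph-regularized posteriors, hidden Markov random
fields) impose the prior that bins in contact should share a label,
which is not generally true.

`hicsaga` avoids the pairwise prior in two steps:

1. **Structural features by graph embedding.** Binned Hi-C counts are
   converted to an observed/expected (O/E) enrichment graph: each
   intra-chromosomal count is divided by the mean count at its bin
   distance on its chromosome, each inter-chromosomal count by the
   global inter mean, and edges with O/E ≥ 1 are kept. Each bin *i*
   gets an embedding vector *u·i* and a context vector *u′·i*, trained
   so that the model distribution

       p₂(j | i) = exp(u′ⱼᵀuᵢ) / Σₖ exp(u′ₖᵀuᵢ)

   matches the empirical neighbour distribution p̂₂(j|i) = wᵢⱼ/dᵢ
   (dᵢ = Σⱼwᵢⱼ), with node weights equal to degree. The resulting
   objective,

       O₂ = − Σ₍ᵢ,ⱼ₎∈E wᵢⱼ log p₂(j | i),

   is optimized by weighted edge sampling with negative sampling
   (5 negatives per positive, noise ∝ degree^0.75). This is a
   **second-order proximity**: bins with similar genome-wide
   interaction profiles — the defining property of a subcompartment —
   embed nearby even if they never touch. Eight dimensions suffice.

2. **Combinatorial annotation by a Gaussian HMM.** The 8 structural
   features are concatenated with the (asinh-transformed, standardized)
   functional tracks and fed to a diagonal-Gaussian hidden Markov model
   over each chromosome; Viterbi decoding yields one domain label per
   bin. Functional-only and structural-only fits provide the single-view
   baselines.

Annotations are scored with variance explained —
VE = 1 − Σdᵢ²/Σ(sᵢ−s̄)², where dᵢ is the residual of predicting each
bin (or gene, or replication-timing phase vector) by its label mean —
and with ChIA-PET loop enrichment: with label coverages C, the expected
same-label loop count is Σᵢ totalO·Cᵢ² and the OE score is
ΣᵢOᵢᵢ/ΣᵢEᵢᵢ. Overlap between annotations is reported as a fold-change
matrix and the adjusted Rand index (ARI).

A fully synthetic data generator plants a factorized truth — a
functional state visible only in the 1D tracks and a structural state
visible only in contact affinities — so the whole pipeline is testable
without any downloads.

## Worked example

```sh
hicsaga simulate --bins 500 --chroms 2 --seed 7 --outdir sim/
hicsaga pipeline --hic sim/contacts.txt --signals sim/signals.tsv \
    --chrom-sizes sim/chrom.sizes --k 6 --seed 7 \
    --genes sim/genes.tsv --loops sim/loops.bedpe --outdir run/
python - <<'EOF'
import json
rep = json.load(open("run/report.json"))
print("gene expression VE:", round(rep["gene_expression_ve"], 3))
print("loop OE:", round(rep["loop_oe"]["loops"]["oe_score"], 3))
print("mean domain length (kb):", round(rep["domain_lengths_bp"]["mean"] / 1e3))
EOF
```

which prints

```
gene expression VE: 0.595
loop OE: 1.836
mean domain length (kb): 1000
```

The combined annotation explains ~60% of the (asinh) gene-expression
variance because the planted combined states carry distinct expression
levels (the remainder is within-state lognormal dispersion); loops were
generated preferring same-structural-state anchors, so same-label loops
are ~1.8× enriched over the coverage expectation; decoded domains
average ~10 bins, consistent with the planted sticky state process
(expected run 10 bins = 1 Mb). Each library function (`compute_oe`, `train`, `annotate`,
`variance_explained`, `loop_enrichment`, …) is importable from
`hicsaga` for use without the CLI.

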