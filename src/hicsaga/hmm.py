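"""Domain annotation by Gaussian-emission mixture / hidden Markov models.

The annotation step is a SAGA (segmentation and genome annotation)
model: each bin's feature vector (functional signal tracks, structural
embedding tracks, or their concatenation) is emitted from one of K
latent domain states; an HMM additionally couples neighbouring bins
along the chromosome, which yields longer, cleaner domains than an
unstructured mixture. Chromosomes are independent observation
sequences, and masked bins split a chromosome into separate sequences
so no transition is learned across gaps.

Model fitting is delegated to hmmlearn (GaussianHMM / GMMHMM) and
scikit-learn (GaussianMixture); this module owns feature preprocessing,
sequence bookkeeping, decoding to per-bin labels, and enrichment-based
state renaming.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GMMHMM, GaussianHMM
from sklearn.mixture import GaussianMixture

from .core import BinnedGenome, DomainAnnotation, FeatureMatrix

VARIANCE_FLOOR = 1e-3  # in post-standardization units
EM_MAX_ITER = 500
EM_REL_TOL = 1e-4


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class Preprocessor:
    """Per-track transform + standardization constants, stored so
    decode-time inputs are transformed exactly like fit-time inputs."""

    transform: str  # asinh_zscore | zscore | none
    keep: np.ndarray  # indices of retained (non-constant) tracks
    means: np.ndarray
    sds: np.ndarray
    track_names: list[str]

    def apply(self, features: FeatureMatrix) -> FeatureMatrix:
        x = features.values[:, self.keep]
        if self.transform == "asinh_zscore":
            x = np.arcsinh(x)
        if self.transform != "none":
            x = (x - self.means) / self.sds
        return FeatureMatrix(x, [self.track_names[k] for k in self.keep], features.mask)


def preprocess(
    features: FeatureMatrix, transform: str = "asinh_zscore"
) -> tuple[FeatureMatrix, Preprocessor]:
    """Standardize tracks over unmasked bins.

    ``asinh_zscore`` applies x -> ln(x + sqrt(x^2+1)) before z-scoring
    (tames heavy-tailed coverage signals); ``zscore`` standardizes
    as-is; ``none`` passes through. Constant tracks are dropped with a
    warning. Standard deviations use denominator n (population).
    """
    if transform not in ("asinh_zscore", "zscore", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    x = features.values.copy()
    if transform == "asinh_zscore":
        x = np.arcsinh(x)
    sub = x[features.mask]
    if transform == "none":
        keep = np.arange(features.n_tracks)
        means = np.zeros(features.n_tracks)
        sds = np.ones(features.n_tracks)
    else:
        means = sub.mean(axis=0)
        sds = sub.std(axis=0)  # ddof=0
        keep = np.flatnonzero(sds > 0)
        if keep.size < features.n_tracks:
            dropped = [
                features.track_names[k]
                for k in range(features.n_tracks)
                if k not in set(keep.tolist())
            ]
            warnings.warn(f"dropping zero-variance track(s): {dropped}")
        means = means[keep]
        sds = sds[keep]
    prep = Preprocessor(transform, keep, means, sds, list(features.track_names))
    return prep.apply(features), prep


# ---------------------------------------------------------------------------
# sequence bookkeeping


def _sequences(genome: BinnedGenome, mask: np.ndarray) -> list[np.ndarray]:
    """Global-bin-index arrays of contiguous unmasked runs, chromosome
    by chromosome (masked bins split sequences)."""
    out = []
    for ci in range(len(genome.chromosomes)):
        sl = genome.chrom_bins(ci)
        m = mask[sl]
        idx = np.arange(sl.start, sl.stop)
        if not m.any():
            continue
        breaks = np.flatnonzero(np.diff(m.astype(int)))
        runs = np.split(idx, breaks + 1)
        out.extend(r for r, keep in zip(runs, np.split(m, breaks + 1)) if keep[0])
    return out


# ---------------------------------------------------------------------------
# models


class _RelativeMonitor(ConvergenceMonitor):
    """Stops EM when the relative log-likelihood improvement drops
    below ``tol``; keeps the full likelihood history."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)

    @property
    def converged(self):
        if self.iter == self.n_iter:
            return True
        if len(self.full_history) < 2:
            return False
        prev, cur = self.full_history[-2], self.full_history[-1]
        denom = abs(prev) if prev != 0 else 1.0
        return (cur - prev) / denom < self.tol


@dataclass
class SagaModel:
    """Fitted annotation model plus its preprocessing record."""

    kind: str  # "hmm" | "gmm"
    K: int
    M: int
    estimator: object
    preprocessors: list[Preprocessor] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)
    loglik: float = float("nan")
    mode: str = ""  # functional | structural | combined
    seed: int = 0


def fit_hmm(
    features: FeatureMatrix,
    genome: BinnedGenome,
    K: int,
    seed: int = 0,
    mixtures: int = 1,
) -> SagaModel:
    """Baum-Welch fit of a K-state diagonal-Gaussian(-mixture) HMM.

    k-means initialization (seeded); EM stops when the relative
    log-likelihood improvement falls below 1e-4 or after 500
    iterations. Raises on a non-finite likelihood.
    """
    _check_fit_inputs(features, K)
    seqs = _sequences(genome, features.mask)
    X = np.vstack([features.values[s] for s in seqs])
    lengths = [s.size for s in seqs]
    if mixtures == 1:
        est = GaussianHMM(
            n_components=K,
            covariance_type="diag",
            min_covar=VARIANCE_FLOOR,
            n_iter=EM_MAX_ITER,
            tol=EM_REL_TOL,
            init_params="stmc",
            params="stmc",
            random_state=seed,
        )
    else:
        est = GMMHMM(
            n_components=K,
            n_mix=mixtures,
            covariance_type="diag",
            n_iter=EM_MAX_ITER,
            tol=EM_REL_TOL,
            init_params="stmcw",
            params="stmcw",
            random_state=seed,
        )
    est.monitor_ = _RelativeMonitor(EM_REL_TOL, EM_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, lengths)
    history = list(est.monitor_.full_history)
    for it, ll in enumerate(history, 1):
        if not np.isfinite(ll):
            raise RuntimeError(f"EM diverged: non-finite log-likelihood at iteration {it}")
    return SagaModel(
        kind="hmm",
        K=K,
        M=mixtures,
        estimator=est,
        loglik_history=history,
        loglik=history[-1] if history else float("nan"),
        seed=seed,
    )


def fit_gmm(features: FeatureMatrix, K: int, seed: int = 0) -> SagaModel:
    """Diagonal-covariance Gaussian mixture (no positional coupling)."""
    _check_fit_inputs(features, K)
    X = features.values[features.mask]
    est = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        reg_covar=VARIANCE_FLOOR,
        max_iter=EM_MAX_ITER,
        tol=EM_REL_TOL,
        init_params="kmeans",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X)
    ll = float(est.score(X) * X.shape[0])
    if not np.isfinite(ll):
        raise RuntimeError("EM diverged: non-finite log-likelihood")
    return SagaModel(kind="gmm", K=K, M=1, estimator=est, loglik=ll, seed=seed)


def _check_fit_inputs(features: FeatureMatrix, K: int) -> None:
    if K < 1:
        raise ValueError("K must be >= 1")
    n_used = int(features.mask.sum())
    if n_used < 10 * K:
        raise ValueError(f"need at least 10*K={10 * K} unmasked bins, got {n_used}")


def decode(
    model: SagaModel, features: FeatureMatrix, genome: BinnedGenome
) -> DomainAnnotation:
    """Viterbi path (HMM) or posterior argmax (GMM) per sequence;
    labels 1..K, masked bins 0."""
    exp_dim = _model_dim(model)
    if features.values.shape[1] != exp_dim:
        raise ValueError(
            f"feature dimension {features.values.shape[1]} != model dimension {exp_dim}"
        )
    labels = np.zeros(genome.n_bins, dtype=np.int32)
    for s in _sequences(genome, features.mask):
        X = features.values[s]
        if model.kind == "hmm":
            states = model.estimator.predict(X)
        else:
            states = model.estimator.predict(X)
        labels[s] = states + 1
    return DomainAnnotation(labels, model.K)


def _model_dim(model: SagaModel) -> int:
    est = model.estimator
    if model.kind == "gmm":
        return est.means_.shape[1]
    if isinstance(est, GMMHMM):
        return est.means_.shape[2]
    return est.means_.shape[1]


def annotate(
    functional: FeatureMatrix | None,
    structural: FeatureMatrix | None,
    genome: BinnedGenome,
    K: int,
    seed: int = 0,
    mixtures: int = 1,
    model_kind: str = "hmm",
) -> tuple[DomainAnnotation, SagaModel]:
    """Fit + decode on functional, structural, or combined features.

    Functional tracks get the asinh + z-score transform, structural
    (embedding) tracks a plain z-score; preprocessed columns are
    concatenated. Input matrices must agree on the bin mask.
    """
    if functional is None and structural is None:
        raise ValueError("at least one of functional/structural is required")
    if (
        functional is not None
        and structural is not None
        and not np.array_equal(functional.mask, structural.mask)
    ):
        raise ValueError(
            "functional and structural masks disagree; harmonize masks first"
        )
    parts, preps = [], []
    if functional is not None:
        f, p = preprocess(functional, "asinh_zscore")
        parts.append(f)
        preps.append(p)
    if structural is not None:
        s, p = preprocess(structural, "zscore")
        parts.append(s)
        preps.append(p)
    combined = parts[0] if len(parts) == 1 else parts[0].hstack(parts[1])
    if model_kind == "hmm":
        model = fit_hmm(combined, genome, K, seed=seed, mixtures=mixtures)
    elif model_kind == "gmm":
        model = fit_gmm(combined, K, seed=seed)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    model.preprocessors = preps
    model.mode = (
        "combined"
        if functional is not None and structural is not None
        else ("functional" if functional is not None else "structural")
    )
    annotation = decode(model, combined, genome)
    return annotation, model


# ---------------------------------------------------------------------------
# enrichment-based renaming


def relabel_by_enrichment(
    annotation: DomainAnnotation,
    reference: DomainAnnotation | None = None,
    ranking_track: np.ndarray | None = None,
) -> DomainAnnotation:
    """Re-index states 1..K so label 1 is the most 'active' state.

    With a reference annotation whose own labels are ordered
    active -> inactive, states sort by descending fold-change
    enrichment in the reference's most active label. With a ranking
    track, states sort by descending state mean of that track. Ties
    break by larger coverage, then original index.
    """
    if (reference is None) == (ranking_track is None):
        raise ValueError("provide exactly one of reference / ranking_track")
    K = annotation.K
    lab = annotation.labels
    ann = annotation.annotated
    cov = annotation.coverage
    metric = np.full(K, -np.inf)
    if ranking_track is not None:
        track = np.asarray(ranking_track, dtype=float)
        for k in range(1, K + 1):
            sel = ann & (lab == k)
            if sel.any():
                metric[k - 1] = track[sel].mean()
    else:
        both = ann & reference.annotated
        if both.sum() < 0.5 * ann.sum():
            warnings.warn("reference covers < 50% of annotated bins")
        p_ref1 = np.mean(reference.labels[both] == 1)
        for k in range(1, K + 1):
            sel = both & (lab == k)
            p_k = sel.sum() / both.sum()
            if p_k > 0 and p_ref1 > 0:
                joint = np.mean((lab[both] == k) & (reference.labels[both] == 1))
                metric[k - 1] = joint / (p_k * p_ref1)
    order = sorted(range(K), key=lambda k: (-metric[k], -cov[k], k))
    remap = np.zeros(K + 1, dtype=np.int32)
    for new, old in enumerate(order, 1):
        remap[old + 1] = new
    return DomainAnnotation(remap[lab], K)


# ---------------------------------------------------------------------------
# JSON serialization


def model_to_json(model: SagaModel, path) -> None:
    est = model.estimator
    doc = {
        "kind": model.kind,
        "K": model.K,
        "M": model.M,
        "mode": model.mode,
        "seed": model.seed,
        "loglik": model.loglik,
        "preprocessors": [
            {
                "transform": p.transform,
                "keep": p.keep.tolist(),
                "means": p.means.tolist(),
                "sds": p.sds.tolist(),
                "track_names": p.track_names,
            }
            for p in model.preprocessors
        ],
    }
    if model.kind == "hmm":
        doc["startprob"] = est.startprob_.tolist()
        doc["transmat"] = est.transmat_.tolist()
        doc["means"] = est.means_.tolist()
        doc["covars"] = np.asarray(est.covars_).tolist()
        if isinstance(est, GMMHMM):
            doc["weights"] = est.weights_.tolist()
    else:
        doc["weights"] = est.weights_.tolist()
        doc["means"] = est.means_.tolist()
        doc["covars"] = est.covariances_.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def model_from_json(path) -> SagaModel:
    with open(path) as fh:
        doc = json.load(fh)
    K, M = doc["K"], doc["M"]
    means = np.asarray(doc["means"])
    if doc["kind"] == "hmm" and M == 1:
        est = GaussianHMM(n_components=K, covariance_type="diag")
        est.startprob_ = np.asarray(doc["startprob"])
        est.transmat_ = np.asarray(doc["transmat"])
        est.means_ = means
        # GaussianHMM.covars_ setter expects the diagonal form
        est.covars_ = np.asarray(doc["covars"])[:, np.arange(means.shape[1]), np.arange(means.shape[1])] if np.asarray(doc["covars"]).ndim == 3 else np.asarray(doc["covars"])
        est.n_features = means.shape[1]
    elif doc["kind"] == "hmm":
        est = GMMHMM(n_components=K, n_mix=M, covariance_type="diag")
        est.startprob_ = np.asarray(doc["startprob"])
        est.transmat_ = np.asarray(doc["transmat"])
        est.means_ = means
        est.covars_ = np.asarray(doc["covars"])
        est.weights_ = np.asarray(doc["weights"])
        est.n_features = means.shape[2]
    else:
        est = GaussianMixture(n_components=K, covariance_type="diag")
        est.weights_ = np.asarray(doc["weights"])
        est.means_ = means
        est.covariances_ = np.asarray(doc["covars"])
        est.precisions_cholesky_ = 1.0 / np.sqrt(est.covariances_)
    model = SagaModel(
        kind=doc["kind"],
        K=K,
        M=M,
        estimator=est,
        loglik=doc.get("loglik", float("nan")),
        mode=doc.get("mode", ""),
        seed=doc.get("seed", 0),
    )
    model.preprocessors = [
        Preprocessor(
            p["transform"],
            np.asarray(p["keep"], dtype=int),
            np.asarray(p["means"]),
            np.asarray(p["sds"]),
            p["track_names"],
        )
        for p in doc.get("preprocessors", [])
    ]
    return model
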