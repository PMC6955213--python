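"""PCA with variance-absorption accounting and a seeded t-SNE sweep.

PCA is computed as the SVD of the (optionally centred/scaled) sample-by-gene
matrix; variance fractions are reported over ALL components so they sum to 1,
which is what the "how many components absorb X% of the variance" question
needs.  The t-SNE sweep runs every (perplexity, seed) combination and keeps
the embedding with the lowest final Kullback-Leibler divergence, ties broken
by the earlier seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .containers import NormalizedMatrix

__all__ = ["PCAResult", "EmbeddingResult", "pca", "components_for_variance", "tsne_sweep"]


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # genes x components
    variance_fractions: np.ndarray  # per component, sums to 1

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame            # samples x (x, y)
    kl_divergence: float
    perplexity: float
    max_iterations: int
    theta: float
    seed: int


def pca(nm: NormalizedMatrix, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal components of samples over genes via SVD.

    ``scale=True`` divides each gene by its sd after centring; a gene with
    zero variance then makes the decomposition undefined and is rejected.
    Components are deterministic up to sign.
    """
    X = nm.values.T.values.astype(float)     # samples x genes
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot scale: constant gene(s) present")
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eig = S ** 2 / max(n - 1, 1)
    total = eig.sum()
    fractions = eig / total if total > 0 else np.zeros_like(eig)
    comps = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=nm.samples, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=nm.genes, columns=comps)
    return PCAResult(scores=scores, loadings=loadings, variance_fractions=fractions)


def components_for_variance(p: PCAResult, target: float) -> int:
    """Smallest number of leading components whose cumulative variance
    fraction reaches ``target``; by convention at least 1."""
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must lie in [0, 1]")
    cum = np.cumsum(p.variance_fractions)
    k = int(np.searchsorted(cum, target - 1e-12) + 1)
    return max(1, min(k, len(cum)))


def tsne_sweep(
    nm: NormalizedMatrix,
    perplexities=(30.0,),
    seeds=(0, 1, 2, 3, 4),
    max_iter: int = 2000,
    theta: float = 0.0,
    pca_dims: int | None = 50,
):
    """Run t-SNE for every (perplexity, seed) pair; return (best, all runs).

    The best run minimises the final KL divergence, ties going to the
    lower-index seed.  ``theta`` = 0 uses the exact gradient; a positive
    value switches to the Barnes-Hut approximation with that angle.
    ``pca_dims`` reduces the input to its leading principal components first
    (the convention of the standard t-SNE tools; ``None`` disables it).
    """
    n = len(nm.samples)
    bound = (n - 1) / 3
    X = nm.values.T.values.astype(float)
    if pca_dims is not None and X.shape[1] > pca_dims:
        comps = min(pca_dims, n - 1)
        X = pca(nm).scores.values[:, :comps]
    results = []
    for perp in perplexities:
        if not 0 < perp < bound:
            raise ValueError(
                f"perplexity must lie in (0, {bound:.2f}) = (n_samples - 1)/3 for n={n}"
            )
        for seed in seeds:
            if theta > 0:
                ts = TSNE(n_components=2, perplexity=perp, max_iter=max_iter,
                          method="barnes_hut", angle=theta, random_state=seed,
                          init="random")
            else:
                ts = TSNE(n_components=2, perplexity=perp, max_iter=max_iter,
                          method="exact", random_state=seed, init="random")
            emb = ts.fit_transform(X)
            coords = pd.DataFrame(emb, index=nm.samples, columns=["x", "y"])
            results.append(EmbeddingResult(
                coords=coords,
                kl_divergence=float(ts.kl_divergence_),
                perplexity=float(perp),
                max_iterations=max_iter,
                theta=theta,
                seed=int(seed),
            ))
    best = min(results, key=lambda r: (r.kl_divergence, list(seeds).index(r.seed)))
    return best, results
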