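"""Thin t-SNE wrapper for visualising genotype structure.

The embedding is run on column-centred dosages and is used for plots
only -- no statistic in the package consumes its output.
"""

from __future__ import annotations

import numpy as np

from ..genotypes import MISSING, GenotypeMatrix

__all__ = ["embed_tsne"]


def embed_tsne(G: GenotypeMatrix, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE coordinates, one row per individual.

    Perplexity defaults to min(30, (n-1)/3) so small panels still embed;
    fewer than 5 individuals is refused.
    """
    from sklearn.manifold import TSNE

    if (G.dosages == MISSING).any():
        raise ValueError("t-SNE needs a complete (imputed) genotype matrix")
    n = G.n_samples
    if n < 5:
        raise ValueError("too few individuals to embed")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    X = G.dosages.astype(float)
    X = X - X.mean(axis=0, keepdims=True)
    return TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(X)
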