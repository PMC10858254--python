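"""Frequency-based imputation of missing genotypes.

Each missing dosage is drawn Binomial(2, p) with p the alternate-allele
frequency among *called* genotypes of the individual's own population at
that locus; a locus entirely missing within a population falls back to the
global called frequency and is logged.  This deliberately ignores linkage
-- at a panel of unlinked SNPs a haplotype model has nothing to exploit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..genotypes import MISSING, GenotypeMatrix

__all__ = ["impute_missing"]


def impute_missing(G: GenotypeMatrix, seed: int = 0):
    """Return (complete GenotypeMatrix, log of global-frequency fallbacks).

    The input is returned unchanged (same object) when nothing is missing.
    """
    if (G.dosages != MISSING).all():
        return G, []

    rng = np.random.default_rng(seed)
    D = G.dosages.copy()
    called = D != MISSING
    pops = G.samples["site"].to_numpy()
    global_p = G.allele_freq()
    fallbacks: list[tuple[str, str]] = []

    for pop in pd.unique(pops):
        rows = pops == pop
        sub = D[rows]
        sub_called = sub != MISSING
        n_called = sub_called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = np.where(
                n_called > 0,
                np.where(sub_called, sub, 0).sum(axis=0) / (2.0 * np.maximum(n_called, 1)),
                np.nan,
            )
        empty = n_called == 0
        if empty.any():
            for j in np.flatnonzero(empty):
                fallbacks.append((str(pop), G.locus_ids[j]))
            p_hat = np.where(empty, global_p, p_hat)
        miss = ~sub_called
        if miss.any():
            probs = np.broadcast_to(p_hat, sub.shape)[miss]
            if np.isnan(probs).any():
                raise ValueError("locus with no called genotypes anywhere")
            sub[miss] = rng.binomial(2, probs).astype(np.int8)
            D[rows] = sub

    return GenotypeMatrix(D, G.samples.copy(), list(G.locus_ids)), fallbacks
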