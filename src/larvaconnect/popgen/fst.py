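"""Weir--Cockerham (1984) F_st with locus-bootstrap significance.

Per locus the three variance components are estimated with unequal sample
sizes: ``a`` among populations, ``b`` among individuals within
populations, ``c`` within individuals.  The multi-locus estimate is the
ratio of sums, theta = sum(a) / sum(a + b + c), which is the standard
combination (per-locus averaging is biased at small locus counts).
Significance of theta > 0 per pair comes from resampling loci with
replacement: P = (#{theta* <= 0} + 1) / (n_boot + 1), one-sided with
add-one smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genotypes import MISSING, GenotypeMatrix

__all__ = [
    "wc_variance_components",
    "weir_cockerham_fst",
    "bootstrap_fst",
    "pairwise_fst",
    "FstResult",
]


def wc_variance_components(dosages: np.ndarray, pop_labels) -> pd.DataFrame:
    """Per-locus Weir--Cockerham components a, b, c over >=2 populations.

    dosages: (n_individuals, n_loci) with -1 missing.  Loci where any
    population has no called genotype, or where the mean sample size is
    <= 1, get NaN components (undefined).
    """
    pop_labels = np.asarray(pop_labels)
    pops = pd.unique(pop_labels)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    L = dosages.shape[1]

    n_i = np.zeros((r, L))       # called individuals per pop
    p_i = np.zeros((r, L))       # allele frequency per pop
    h_i = np.zeros((r, L))       # observed heterozygote fraction per pop
    for k, pop in enumerate(pops):
        sub = dosages[pop_labels == pop]
        called = sub != MISSING
        nk = called.sum(axis=0)
        n_i[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(nk > 0, np.where(called, sub, 0).sum(axis=0) / (2.0 * np.maximum(nk, 1)), np.nan)
            h_i[k] = np.where(nk > 0, ((sub == 1) & called).sum(axis=0) / np.maximum(nk, 1), np.nan)

    n_bar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    undefined = (n_i == 0).any(axis=0) | (n_bar <= 1) | ~np.isfinite(n_c) | (n_c <= 0)
    a = np.where(undefined, np.nan, a)
    b = np.where(undefined, np.nan, b)
    c = np.where(undefined, np.nan, c)
    return pd.DataFrame({"a": a, "b": b, "c": c})


def weir_cockerham_fst(G: GenotypeMatrix, pop_labels=None, pair=None) -> dict:
    """Multi-locus theta for one population pair (or all populations).

    Returns a dict with per-locus components, the boolean mask of loci
    entering the ratio (defined components with a non-zero denominator),
    the ids of excluded loci, and the estimate.
    """
    labels = np.asarray(pop_labels if pop_labels is not None else G.samples["site"])
    dosages = G.dosages
    if pair is not None:
        keep = np.isin(labels, list(pair))
        dosages = dosages[keep]
        labels = labels[keep]
        for p in pair:
            if ((labels == p) & ((dosages != MISSING).any(axis=1))).sum() < 2:
                raise ValueError(f"population {p!r} has fewer than 2 called individuals")
    comp = wc_variance_components(dosages, labels)
    denom = comp["a"] + comp["b"] + comp["c"]
    used = np.isfinite(denom.to_numpy()) & (denom.to_numpy() != 0)
    if not used.any():
        raise ValueError("no informative loci for this pair")
    theta = float(comp.loc[used, "a"].sum() / denom[used].sum())
    excluded = [G.locus_ids[i] for i in np.flatnonzero(~used)]
    return {"components": comp, "used": used, "excluded_loci": excluded, "fst": theta}


def bootstrap_fst(
    G: GenotypeMatrix, pop_labels=None, pair=None, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Locus bootstrap for one pair: point estimate, one-sided P for
    theta > 0, and the percentile 95% CI.  Seeded and reproducible."""
    res = weir_cockerham_fst(G, pop_labels, pair)
    comp = res["components"].to_numpy()[res["used"]]
    n_loci = comp.shape[0]
    if n_loci < 2:
        raise ValueError("need at least 2 informative loci to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    a = comp[:, 0][idx].sum(axis=1)
    abc = comp.sum(axis=1)[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = np.where(abc != 0, a / abc, 0.0)
    p_value = (int((thetas <= 0).sum()) + 1) / (n_boot + 1)
    ci = (float(np.percentile(thetas, 2.5)), float(np.percentile(thetas, 97.5)))
    return {
        "fst": res["fst"],
        "p_value": p_value,
        "ci95": ci,
        "replicates": thetas,
        "n_boot": n_boot,
        "excluded_loci": res["excluded_loci"],
    }


@dataclass
class FstResult:
    """Pairwise divergence over all site pairs.

    ``fst`` is symmetric with a zero diagonal; ``p_values`` carries the
    one-sided bootstrap P per pair; ``significant`` flags P < alpha.
    """

    sites: list
    fst: pd.DataFrame
    p_values: pd.DataFrame
    n_bootstrap: int = 1000
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        sig = self.p_values < self.alpha
        np.fill_diagonal(sig.values, False)
        return sig

    def long_table(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.sites):
            for j, b in enumerate(self.sites):
                if j <= i:
                    continue
                rows.append(
                    {
                        "site_a": a,
                        "site_b": b,
                        "fst": self.fst.iloc[i, j],
                        "p_value": self.p_values.iloc[i, j],
                        "significant": bool(self.p_values.iloc[i, j] < self.alpha),
                    }
                )
        return pd.DataFrame(rows)


def pairwise_fst(G: GenotypeMatrix, n_boot: int = 1000, seed: int = 0) -> FstResult:
    """Weir--Cockerham theta with bootstrap P for every pair of sites."""
    sites = list(pd.unique(G.samples["site"]))
    k = len(sites)
    if k < 2:
        raise ValueError("pairwise statistics need >= 2 populations")
    fst = np.zeros((k, k))
    pvals = np.ones((k, k))
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.generate_state(k * k)
    for i in range(k):
        for j in range(i + 1, k):
            b = bootstrap_fst(G, pair=(sites[i], sites[j]), n_boot=n_boot, seed=int(pair_seeds[i * k + j]))
            fst[i, j] = fst[j, i] = b["fst"]
            pvals[i, j] = pvals[j, i] = b["p_value"]
    return FstResult(
        sites,
        pd.DataFrame(fst, index=sites, columns=sites),
        pd.DataFrame(pvals, index=sites, columns=sites),
        n_bootstrap=n_boot,
    )
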