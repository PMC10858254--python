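"""Locus filtering: call rate, minor allele frequency, Hardy--Weinberg.

The rules and their boundary semantics follow the common variant-QC
convention for reduced-representation SNP panels: keep a locus if it is
called in at least half the individuals (inclusive), its minor allele
frequency is strictly over 0.05, and a 1-df chi-square Hardy--Weinberg
test does not reject at P < 1e-8 (inclusive keep at the threshold).
Rules are applied in that order and the audit log names the first rule a
dropped locus failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..genotypes import MISSING, GenotypeMatrix

__all__ = ["FilterConfig", "hwe_chisq_pvalue", "filter_loci"]


@dataclass(frozen=True)
class FilterConfig:
    min_call_fraction: float = 0.5
    min_maf: float = 0.05
    hwe_p_threshold: float = 1e-8

    def __post_init__(self):
        for name in ("min_call_fraction", "min_maf", "hwe_p_threshold"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def hwe_chisq_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-degree-of-freedom chi-square goodness-of-fit test of
    Hardy--Weinberg proportions.

    Expected genotype counts come from the estimated allele frequency; a
    monomorphic locus fits HWE trivially and returns (0, 1).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def filter_loci(G: GenotypeMatrix, config: FilterConfig | None = None):
    """Apply the three QC rules in order; return (filtered matrix, audit log).

    The audit log is one row per input locus with the computed call
    fraction, MAF and HWE P-value, a ``kept`` flag and, for dropped loci,
    the first failing rule ("call_rate", "maf" or "hwe").
    """
    cfg = config or FilterConfig()
    D = G.dosages
    called = D != MISSING
    call_frac = called.mean(axis=0)
    maf = G.maf()

    chi2s = np.zeros(G.n_loci)
    pvals = np.ones(G.n_loci)
    for j in range(G.n_loci):
        col = D[called[:, j], j]
        if col.size:
            chi2s[j], pvals[j] = hwe_chisq_pvalue(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )

    reason = np.full(G.n_loci, "", dtype=object)
    fail_call = call_frac < cfg.min_call_fraction
    fail_maf = ~fail_call & ~(maf > cfg.min_maf)
    fail_hwe = ~fail_call & ~fail_maf & (pvals < cfg.hwe_p_threshold)
    reason[fail_call] = "call_rate"
    reason[fail_maf] = "maf"
    reason[fail_hwe] = "hwe"
    kept = reason == ""

    audit = pd.DataFrame(
        {
            "locus": G.locus_ids,
            "call_fraction": call_frac,
            "maf": maf,
            "hwe_chi2": chi2s,
            "hwe_p": pvals,
            "kept": kept,
            "reason": np.where(kept, None, reason),
        }
    ).set_index("locus")
    if not kept.any():
        import warnings

        warnings.warn("all loci removed by filtering", stacklevel=2)
    return G.subset_loci(kept), audit
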