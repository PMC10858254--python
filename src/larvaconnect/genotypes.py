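"""Diploid biallelic genotype matrices and their synthetic generator.

Dosages are counts of the alternate allele (0/1/2) with -1 for missing.
Sample metadata carries a site (population) label and a life-stage label
(adult or spat; in the sampling design these proxy successive
generations).

The generator draws hierarchical population structure from the
Balding--Nichols model: subpopulation allele frequencies are Beta
distributed around an ancestral frequency p with variance p(1-p)F, so the
divergence parameter F is a closed-form F_st target and estimation on the
output is a parameter-recovery exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PopGenSimConfig", "simulate_genotypes"]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosages with sample metadata.

    dosages : int8 array (n_samples, n_loci), values in {0, 1, 2, -1}.
    samples : DataFrame indexed by sample id with at least columns
              ``site`` and ``stage``.
    locus_ids : per-locus identifiers.
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    locus_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or -1 for missing")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample table does not match dosage rows")
        if not self.locus_ids:
            self.locus_ids = [f"snp{i:05d}" for i in range(self.dosages.shape[1])]
        if len(self.locus_ids) != self.dosages.shape[1]:
            raise ValueError("locus_ids do not match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def called(self) -> np.ndarray:
        return self.dosages != MISSING

    def call_fraction(self) -> np.ndarray:
        """Per-locus fraction of non-missing genotypes."""
        return self.called.mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency among called genotypes
        (NaN where nothing is called)."""
        called = self.called
        n_called = called.sum(axis=0)
        tot = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, tot / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        ids = [self.locus_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool else [
            self.locus_ids[i] for i in keep
        ]
        return GenotypeMatrix(self.dosages[:, keep], self.samples.copy(), ids)

    def subset_samples(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(self.dosages[keep], self.samples.iloc[keep].copy(), list(self.locus_ids))


@dataclass(frozen=True)
class PopGenSimConfig:
    """Conditions for the synthetic SNP panel.

    Defaults mirror the sampling design this package emulates: 13 sites of
    ~40 mussels each (520 individuals) typed at 552 informative markers,
    with modest divergence and missingness typical of a reduced-
    representation panel after filtering.

    target_fst may be a scalar (shared by all subpopulations) or a
    per-subpopulation sequence of Balding--Nichols divergence parameters.
    admixture_Q, when given, is an (individuals x K) matrix of ancestry
    proportions; cluster allele frequencies are then drawn for K clusters
    and each individual's allele probability is the Q-weighted mixture.
    """

    n_pops: int = 13
    n_per_pop: int = 40
    n_loci: int = 552
    target_fst: object = 0.05
    admixture_Q: object = None
    missing_rate: float = 0.05
    spat_fraction: float = 0.3
    seed: int = 0

    def fst_array(self, k: int) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.target_fst, dtype=float), (k,)).copy()
        if ((f < 0) | (f >= 1)).any():
            raise ValueError("target_fst must lie in [0, 1)")
        return f

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.spat_fraction <= 1:
            raise ValueError("spat_fraction must lie in [0, 1]")
        if min(self.n_pops, self.n_per_pop, self.n_loci) <= 0:
            raise ValueError("counts must be positive")
        self.fst_array(self.n_pops)  # validates
        if self.admixture_Q is not None:
            Q = np.asarray(self.admixture_Q, dtype=float)
            if Q.ndim != 2 or Q.shape[0] != self.n_pops * self.n_per_pop:
                raise ValueError("admixture_Q must be (n_individuals, K)")
            if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("admixture_Q rows must sum to 1")


def _balding_nichols(rng, p_anc: np.ndarray, F: float) -> np.ndarray:
    """Subpopulation frequencies Beta(p(1-F)/F, (1-p)(1-F)/F); F=0 returns
    the ancestral frequencies unchanged."""
    if F == 0.0:
        return p_anc.copy()
    scale = (1.0 - F) / F
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def simulate_genotypes(config: PopGenSimConfig, return_truth: bool = False):
    """Draw a :class:`GenotypeMatrix` under the Balding--Nichols model.

    Ancestral frequencies are uniform on [0.05, 0.95]; each subpopulation
    (or admixture cluster) gets Beta-perturbed frequencies at its
    divergence parameter; genotypes are Binomial(2, p) per individual x
    locus; missing entries are assigned completely at random.  With
    ``return_truth`` the generating frequencies and ancestry matrix are
    returned alongside for parameter-recovery testing.
    """
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_pops * config.n_per_pop
    L = config.n_loci

    p_anc = rng.uniform(0.05, 0.95, size=L)

    if config.admixture_Q is not None:
        Q = np.asarray(config.admixture_Q, dtype=float)
        K = Q.shape[1]
        F = config.fst_array(K)
        pop_freqs = np.stack([_balding_nichols(rng, p_anc, F[k]) for k in range(K)])
        probs = Q @ pop_freqs  # (n_ind, L)
    else:
        K = config.n_pops
        F = config.fst_array(K)
        pop_freqs = np.stack([_balding_nichols(rng, p_anc, F[k]) for k in range(K)])
        pop_of = np.repeat(np.arange(K), config.n_per_pop)
        probs = pop_freqs[pop_of]
        Q = None

    dosages = rng.binomial(2, probs).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING

    pop_of = np.repeat(np.arange(config.n_pops), config.n_per_pop)
    stage = np.where(rng.random(n_ind) < config.spat_fraction, "spat", "adult")
    samples = pd.DataFrame(
        {
            "site": [f"pop{k}" for k in pop_of],
            "stage": stage,
        },
        index=[f"ind{i:04d}" for i in range(n_ind)],
    )
    G = GenotypeMatrix(dosages, samples)
    if return_truth:
        return G, {"p_anc": p_anc, "pop_freqs": pop_freqs, "Q": Q, "pop_of": pop_of}
    return G
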