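"""Maximum-likelihood admixture via expectation--maximisation.

Model: individual i carries ancestry proportions q_i over K clusters with
cluster allele frequencies p_k; each of the two allele copies at locus l
is the alternate allele with probability f_il = sum_k q_ik p_kl, so the
dosage g_il ~ Binomial(2, f_il).  The EM updates are the classic ones for
this likelihood and increase it monotonically; several seeded restarts
guard against local optima.

K is chosen by masked-entry cross-validation: a random fraction of
observed dosages is held out per fold, the model is fitted on the rest,
and the held-out entries are scored under the fitted binomial; the K
maximising the mean held-out log-likelihood is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ..genotypes import MISSING, GenotypeMatrix

__all__ = ["AdmixtureResult", "admixture_em", "select_K", "align_Q"]

_EPS = 1e-9
_LOG2 = np.log(2.0)


@dataclass
class AdmixtureResult:
    """Fitted admixture model for one K."""

    K: int
    Q: pd.DataFrame            # individuals x K, rows on the simplex
    P_alleles: np.ndarray      # K x loci cluster allele frequencies
    log_likelihood: float
    loglik_path: np.ndarray = field(repr=False, default=None)
    n_iter: int = 0
    converged: bool = False

    def argmax_labels(self) -> pd.Series:
        """Hard cluster per individual (largest ancestry share)."""
        return pd.Series(self.Q.to_numpy().argmax(axis=1), index=self.Q.index, name="cluster")


def _binom_loglik(G, W, F):
    """Full binomial log-likelihood of observed entries (coefficient included)."""
    F = np.clip(F, _EPS, 1 - _EPS)
    ll = W * (G * np.log(F) + (2 - G) * np.log(1 - F))
    return float(ll.sum() + _LOG2 * ((G == 1) & (W > 0)).sum())


def _em_once(G, W, K, rng, tol, max_iter):
    n, L = G.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.05, 0.95, size=(K, L))
    prev = -np.inf
    path = []
    obs_per_ind = 2.0 * W.sum(axis=1)  # allele copies observed per individual
    for it in range(max_iter):
        F = np.clip(Q @ P, _EPS, 1 - _EPS)
        new_Q = np.zeros_like(Q)
        new_P_num = np.zeros_like(P)
        new_P_den = np.zeros_like(P)
        Galt = G * W
        Gref = (2 - G) * W
        for k in range(K):
            # expected alternate / reference allele copies attributed to cluster k
            alt_k = Galt * (Q[:, k:k + 1] * P[k]) / F
            ref_k = Gref * (Q[:, k:k + 1] * (1 - P[k])) / (1 - F)
            new_P_num[k] = alt_k.sum(axis=0)
            new_P_den[k] = alt_k.sum(axis=0) + ref_k.sum(axis=0)
            new_Q[:, k] = (alt_k + ref_k).sum(axis=1)
        P = np.clip(np.where(new_P_den > 0, new_P_num / np.maximum(new_P_den, _EPS), 0.5), _EPS, 1 - _EPS)
        Q = new_Q / np.maximum(obs_per_ind[:, None], _EPS)
        Q = np.clip(Q, _EPS, None)
        Q /= Q.sum(axis=1, keepdims=True)

        ll = _binom_loglik(G, W, Q @ P)
        if ll < prev - 1e-6:
            raise RuntimeError(f"EM log-likelihood decreased: {prev} -> {ll}")
        path.append(ll)
        if prev > -np.inf and abs(ll - prev) <= tol * abs(prev):
            return Q, P, ll, np.array(path), it + 1, True
        prev = ll
    return Q, P, prev, np.array(path), max_iter, False


def admixture_em(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    _mask: np.ndarray | None = None,
) -> AdmixtureResult:
    """Fit the K-cluster admixture model by EM with seeded restarts.

    Missing dosages (and any entries excluded via ``_mask``) carry zero
    weight in the likelihood.  K = 1 reduces to the closed form: Q is all
    ones and the cluster frequencies are the observed allele frequencies.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    D = G.dosages.astype(float)
    W = (G.dosages != MISSING).astype(float)
    if _mask is not None:
        W = W * (~_mask)
    Gm = np.where(W > 0, D, 0.0)

    if K == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = Gm.sum(axis=0) / np.maximum(2.0 * W.sum(axis=0), _EPS)
        P = np.clip(p[None, :], _EPS, 1 - _EPS)
        ll = _binom_loglik(Gm, W, np.ones((G.n_samples, 1)) @ P)
        Q = pd.DataFrame(np.ones((G.n_samples, 1)), index=G.samples.index)
        return AdmixtureResult(1, Q, P, ll, np.array([ll]), 1, True)

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        Q, P, ll, path, n_iter, conv = _em_once(Gm, W, K, rng, tol, max_iter)
        if best is None or ll > best[2]:
            best = (Q, P, ll, path, n_iter, conv)
    Q, P, ll, path, n_iter, conv = best
    if not np.isfinite(ll):
        raise RuntimeError("non-finite likelihood")
    return AdmixtureResult(
        K, pd.DataFrame(Q, index=G.samples.index), P, ll, path, n_iter, conv
    )


def select_K(
    G: GenotypeMatrix,
    K_range,
    n_folds: int = 5,
    seed: int = 0,
    mask_fraction: float = 0.05,
    tol: float = 1e-5,
    max_iter: int = 300,
    n_restarts: int = 3,
    fit_full: bool = True,
) -> dict:
    """Choose K by masked-entry cross-validation.

    Per fold a random ``mask_fraction`` of *observed* dosages is hidden;
    the model fitted on the rest scores the hidden entries.  Returns the
    chosen K, the per-(K, fold) held-out mean log-likelihood table, and a
    full-data fit per K.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range is empty")
    n_plausible = len(pd.unique(G.samples["site"]))
    if max(K_range) > max(n_plausible, 1) + 2:
        import warnings

        warnings.warn(
            f"K up to {max(K_range)} may not be identifiable with {n_plausible} sites",
            stacklevel=2,
        )
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(n_folds)
    fit_seeds = ss.spawn(len(K_range))
    observed = G.dosages != MISSING
    obs_idx = np.argwhere(observed)
    D = G.dosages.astype(float)

    scores = np.zeros((len(K_range), n_folds))
    for f, fseed in enumerate(fold_seeds):
        rng = np.random.default_rng(fseed)
        n_mask = max(1, int(round(mask_fraction * obs_idx.shape[0])))
        pick = rng.choice(obs_idx.shape[0], size=n_mask, replace=False)
        mask = np.zeros_like(observed)
        mask[obs_idx[pick, 0], obs_idx[pick, 1]] = True
        for ki, K in enumerate(K_range):
            fit = admixture_em(
                G, K, seed=int(fit_seeds[ki].generate_state(1)[0]),
                tol=tol, max_iter=max_iter, n_restarts=n_restarts, _mask=mask,
            )
            F = np.clip(fit.Q.to_numpy() @ fit.P_alleles, _EPS, 1 - _EPS)
            g = D[mask]
            fm = F[mask]
            ll = g * np.log(fm) + (2 - g) * np.log(1 - fm) + (g == 1) * _LOG2
            scores[ki, f] = float(ll.mean())

    table = pd.DataFrame(scores, index=K_range, columns=[f"fold{f}" for f in range(n_folds)])
    table["mean"] = table.mean(axis=1)
    chosen = int(table["mean"].idxmax())
    fits = {}
    if fit_full:
        fits = {
            K: admixture_em(
                G, K, seed=int(fit_seeds[ki].generate_state(2)[1]),
                tol=tol, max_iter=max_iter, n_restarts=n_restarts,
            )
            for ki, K in enumerate(K_range)
        }
    return {"chosen_K": chosen, "scores": table, "fits": fits}


def align_Q(Q_est: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute estimated clusters to best match a reference ancestry matrix
    (Hungarian assignment on column-wise L1 cost); returns Q_est reordered."""
    K = Q_true.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(Q_est[:, i] - Q_true[:, j]).sum()
    rows, cols = linear_sum_assignment(cost)
    order = np.empty(K, dtype=int)
    order[cols] = rows
    return Q_est[:, order]
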