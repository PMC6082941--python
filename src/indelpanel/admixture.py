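"""Bayesian admixture-model clustering for diallelic loci (a desk-scale
STRUCTURE-style Gibbs sampler).

Model: individual i draws each of its two allele copies at locus l from a
cluster z chosen with probability Q[i, k], then the allele from that
cluster's insertion frequency P[k, l].  Priors are the simplest standard
variant: fixed symmetric Dirichlet(alpha) on the rows of Q (alpha = 1 by
default, no alpha inference) and uncorrelated Beta(1, 1) priors on the
cluster allele frequencies.  All updates are conjugate:

* z   ~ Categorical(Q[i, :] * allele likelihood)   per allele copy
* P   ~ Beta(1 + insertion copies in k, 1 + deletion copies in k)
* Q_i ~ Dirichlet(alpha + copy-assignment counts of i)

By default the Dirichlet concentration alpha is itself inferred with a
Metropolis random-walk step under a Uniform(0, 10) prior, the behaviour
of STRUCTURE's admixture model: for well-separated populations alpha
shrinks well below 1 and the ancestry proportions of unadmixed
individuals concentrate accordingly.  Passing a numeric ``alpha`` fixes
it instead.

Posterior means over post-burn-in sweeps are returned.  The sampler is
fully reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, QMatrix


@dataclass
class AdmixtureFit:
    """Posterior summary of one admixture run."""

    K: int
    Q: QMatrix
    cluster_allele_freqs: np.ndarray  # (K, L) insertion frequencies
    log_likelihood_trace: np.ndarray  # one entry per Gibbs sweep
    burn_in: int
    reps: int
    seed: int
    alpha_mean: float = float("nan")  # posterior mean concentration (if inferred)


def _allele_copies(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(2, n, L) allele array (1 = insertion) and validity mask.

    Unphased heterozygotes are split arbitrarily (one insertion copy, one
    deletion copy); the admixture likelihood does not depend on phase.
    """
    calls = gm.calls
    if np.any((calls < -1) | (calls > 2)):
        raise ValueError("non-diallelic call codes present")
    mask = calls != MISSING
    a0 = (calls >= 1).astype(np.int8)
    a1 = (calls == 2).astype(np.int8)
    alleles = np.stack([a0, a1])
    return alleles, np.stack([mask, mask])


def admixture_log_likelihood(
    gm: GenotypeMatrix, Q: np.ndarray, P: np.ndarray
) -> float:
    """Observed-data log-likelihood of (Q, P) under the admixture model."""
    alleles, mask = _allele_copies(gm)
    Pc = np.clip(P, 1e-12, 1 - 1e-12)
    # per-copy mixture probability sum_k Q[i,k] * (P or 1-P)[k,l]
    total = 0.0
    for c in range(2):
        p_ins = Q @ Pc  # (n, L)
        p_del = Q @ (1 - Pc)
        per_copy = np.where(alleles[c] == 1, p_ins, p_del)
        total += float(np.log(per_copy[mask[c]]).sum())
    return total


_ALPHA_MAX = 10.0
_ALPHA_PROPOSAL_SD = 0.05


def _log_dirichlet_sym(alpha: float, log_q_sum: float, n: int, K: int) -> float:
    """Log density (up to data terms) of n symmetric Dirichlet(alpha) rows."""
    from scipy.special import gammaln

    return n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1.0) * log_q_sum


def structure_fit(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int = 10_000,
    reps: int = 10_000,
    seed: int | None = None,
    alpha: float | None = None,
) -> AdmixtureFit:
    """Gibbs sampler for the admixture model at a fixed number of clusters.

    Parameters
    ----------
    gm
        Diallelic genotype matrix.
    K
        Number of ancestral clusters (>= 1).
    burn_in, reps
        Discarded sweeps and retained sweeps; posterior means are taken
        over the ``reps`` post-burn-in sweeps.
    seed
        Mandatory RNG seed.
    alpha
        Symmetric Dirichlet concentration on ancestry proportions.  The
        default (``None``) infers it by a Metropolis random walk under a
        Uniform(0, 10) prior; a float fixes it.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    n, L = gm.n_samples, gm.n_loci
    alleles, mask = _allele_copies(gm)

    # initial state: frequencies near the pooled sample frequency, even Q
    obs = mask[0]
    with np.errstate(invalid="ignore"):
        pooled = np.where(
            obs.sum(axis=0) > 0,
            np.where(obs, gm.calls, 0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)),
            0.5,
        )
    P = np.clip(
        pooled[None, :] + rng.normal(0.0, 0.01, size=(K, L)), 0.01, 0.99
    )
    Q = np.full((n, K), 1.0 / K)

    infer_alpha = alpha is None
    alpha_cur = 1.0 if infer_alpha else float(alpha)
    if alpha_cur <= 0:
        raise ValueError("alpha must be positive")

    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L))
    alpha_sum = 0.0
    trace = np.empty(burn_in + reps)

    for sweep in range(burn_in + reps):
        # --- sample per-copy cluster assignments -------------------------
        ins_counts = np.zeros((K, L))
        del_counts = np.zeros((K, L))
        q_counts = np.zeros((n, K))
        for c in range(2):
            lik = np.where(
                alleles[c][:, :, None] == 1, P.T[None, :, :], (1 - P).T[None, :, :]
            )  # (n, L, K)
            w = Q[:, None, :] * lik
            w_sum = w.sum(axis=2, keepdims=True)
            prob = w / w_sum
            u = rng.random((n, L, 1))
            z = (u > np.cumsum(prob, axis=2)).sum(axis=2)  # (n, L) in [0, K)
            for k in range(K):
                zk = (z == k) & mask[c]
                ins_counts[k] += (zk & (alleles[c] == 1)).sum(axis=0)
                del_counts[k] += (zk & (alleles[c] == 0)).sum(axis=0)
                q_counts[:, k] += zk.sum(axis=1)
        # --- conjugate updates -------------------------------------------
        P = rng.beta(1.0 + ins_counts, 1.0 + del_counts)
        g = rng.gamma(alpha_cur + q_counts)
        Q = g / g.sum(axis=1, keepdims=True)
        if infer_alpha and K > 1:
            log_q_sum = float(np.log(np.clip(Q, 1e-300, None)).sum())
            prop = rng.normal(alpha_cur, _ALPHA_PROPOSAL_SD)
            if 0.0 < prop < _ALPHA_MAX:
                delta = _log_dirichlet_sym(prop, log_q_sum, n, K) - _log_dirichlet_sym(
                    alpha_cur, log_q_sum, n, K
                )
                if np.log(rng.random()) < delta:
                    alpha_cur = prop
        # --- bookkeeping ---------------------------------------------------
        trace[sweep] = admixture_log_likelihood(gm, Q, P)
        if sweep >= burn_in:
            q_sum += Q
            p_sum += P
            alpha_sum += alpha_cur

    q_mean = q_sum / reps
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    return AdmixtureFit(
        K=K,
        Q=QMatrix(list(gm.sample_ids), q_mean),
        cluster_allele_freqs=p_sum / reps,
        log_likelihood_trace=trace,
        burn_in=burn_in,
        reps=reps,
        seed=seed,
        alpha_mean=alpha_sum / reps,
    )


def align_runs(fits: list[AdmixtureFit]) -> list[AdmixtureFit]:
    """Resolve label switching across runs of the same K.

    Greedily permutes each run's clusters to maximize the summed
    correlation of Q columns against the first run; deterministic.
    """
    if not fits:
        return []
    if len({f.K for f in fits}) != 1:
        raise ValueError("all fits must share the same K")
    ref = fits[0].Q.proportions
    K = fits[0].K
    aligned = [fits[0]]
    for fit in fits[1:]:
        q = fit.Q.proportions
        perm = [-1] * K
        used: set[int] = set()
        # greedy: repeatedly take the best remaining (ref col, run col) match
        scores = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                ri, qj = ref[:, i], q[:, j]
                if ri.std() == 0 or qj.std() == 0:
                    scores[i, j] = -np.inf if i != j else 0.0
                else:
                    scores[i, j] = float(np.corrcoef(ri, qj)[0, 1])
        flat = sorted(
            ((i, j) for i in range(K) for j in range(K)),
            key=lambda ij: (-scores[ij], ij),
        )
        taken_ref: set[int] = set()
        for i, j in flat:
            if i in taken_ref or j in used:
                continue
            perm[i] = j
            taken_ref.add(i)
            used.add(j)
        order = perm
        aligned.append(
            AdmixtureFit(
                K=fit.K,
                Q=QMatrix(fit.Q.sample_ids, q[:, order]),
                cluster_allele_freqs=fit.cluster_allele_freqs[order],
                log_likelihood_trace=fit.log_likelihood_trace,
                burn_in=fit.burn_in,
                reps=fit.reps,
                seed=fit.seed,
            )
        )
    return aligned


def membership_barchart_data(
    fit: AdmixtureFit, population_labels: list[str]
) -> pd.DataFrame:
    """Per-population mean ancestry components plus sample sizes.

    The ``n`` column supports bar widths proportional to sample size in a
    stacked membership chart.
    """
    q = fit.Q.to_frame()
    q["population"] = list(population_labels)
    means = q.groupby("population", sort=False).mean()
    means["n"] = q.groupby("population", sort=False).size()
    return means
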