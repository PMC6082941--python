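"""Hardy-Weinberg testing and pairwise linkage disequilibrium for
diallelic loci.

The exact HWE test is the Levene-Haldane conditional test: holding the
observed allele counts fixed, every compatible heterozygote count h has
conditional probability

    P(h | n, n_I) = 2^h * n! * n_I! * n_D! / ((2n)! * n_II! * h! * n_DD!)

and the two-sided p-value is the sum of P over configurations no more
probable than the observed one.

Pairwise LD uses EM haplotype-frequency estimation from unphased
two-locus genotypes (only the double heterozygote is phase-ambiguous),
then D = f_II - p1 p2, D' = |D| / Dmax and r^2 = D^2 / (p1 q1 p2 q2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .types import (
    MISSING,
    DD,
    ID,
    II,
    DegenerateInputError,
    GenotypeMatrix,
    LocusCounts,
)

_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def _het_log_probs(n: int, n_ins: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of every compatible het count."""
    n_del = 2 * n - n_ins
    h_max = min(n_ins, n_del)
    hets = np.arange(n_ins % 2, h_max + 1, 2)
    n_ii = (n_ins - hets) // 2
    n_dd = (n_del - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        + gammaln(n_ins + 1)
        + gammaln(n_del + 1)
        - gammaln(2 * n + 1)
        - gammaln(n_ii + 1)
        - gammaln(hets + 1)
        - gammaln(n_dd + 1)
    )
    return hets, logp


def hwe_exact(c: LocusCounts) -> float:
    """Two-sided Levene-Haldane exact HWE p-value.

    Monomorphic loci (or empty counts) return 1.0.
    """
    if c.n == 0:
        return 1.0
    n_ins = c.n_insertion
    if n_ins == 0 or n_ins == 2 * c.n:
        return 1.0
    hets, logp = _het_log_probs(c.n, n_ins)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, c.n_ID)]
    # small relative slack guards against float noise in the tie comparison
    return min(1.0, float(probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_chi2(c: LocusCounts) -> tuple[float, float]:
    """One-df chi-square HWE test against p^2, 2pq, q^2 expectations."""
    if c.n == 0:
        raise DegenerateInputError("no genotypes")
    p = c.n_insertion / (2.0 * c.n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * c.n
    observed = np.array([c.n_II, c.n_ID, c.n_DD], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return stat, float(chi2_dist.sf(stat, df=1))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("need at least one test")
    return alpha / m


@dataclass
class HWEResult:
    locus_id: str
    p_exact: float
    p_chi2: float
    chi2: float
    significant_after_bonferroni: bool


def hwe_screen(gm: GenotypeMatrix, alpha: float = 0.05) -> list[HWEResult]:
    """Exact and chi-square HWE tests for every locus, Bonferroni-flagged."""
    from .forensic import locus_counts

    threshold = bonferroni_threshold(alpha, gm.n_loci)
    out = []
    for locus in gm.locus_ids:
        c = locus_counts(gm, locus)
        p_exact = hwe_exact(c)
        if c.n and 0 < c.n_insertion < 2 * c.n:
            stat, p_chi2 = hwe_chi2(c)
        else:
            stat, p_chi2 = 0.0, 1.0
        out.append(HWEResult(locus, p_exact, p_chi2, stat, p_exact < threshold))
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def pair_counts(gm: GenotypeMatrix, locus_a: str, locus_b: str) -> np.ndarray:
    """3x3 table of two-locus genotype-pair counts.

    Rows index the genotype at ``locus_a`` and columns at ``locus_b``, both
    ordered II, ID, DD.  Individuals missing at either locus are excluded.
    """
    a = gm.calls[:, gm.locus_index(locus_a)]
    b = gm.calls[:, gm.locus_index(locus_b)]
    keep = (a != MISSING) & (b != MISSING)
    table = np.zeros((3, 3), dtype=int)
    # dosage 2/1/0 maps to row/col 0/1/2
    for ga, gb in zip(a[keep], b[keep]):
        table[2 - ga, 2 - gb] += 1
    return table


def em_haplotype_freqs(
    table: np.ndarray, return_trace: bool = False
) -> "np.ndarray | tuple[np.ndarray, list[np.ndarray]]":
    """Maximum-likelihood haplotype frequencies (I-I, I-D, D-I, D-D) by EM.

    ``table`` is the 3x3 genotype-pair count table from :func:`pair_counts`.
    Only the double heterozygote carries phase ambiguity; its expected split
    between the coupling (II/DD) and repulsion (ID/DI) phases is refreshed
    from the current haplotype frequencies each iteration.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise DegenerateInputError("empty genotype-pair table")
    # haplotype copies contributed unambiguously by each cell
    # cell (i, j): locus A dosage 2-i, locus B dosage 2-j
    n_dh = table[1, 1]  # double heterozygotes
    base = np.zeros(4)  # I-I, I-D, D-I, D-D copies
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            cnt = table[i, j]
            a_ins, b_ins = 2 - i, 2 - j
            # each individual carries two haplotypes; for single-locus hets
            # phase is irrelevant to haplotype identity
            a_alleles = [1] * a_ins + [0] * (2 - a_ins)
            b_alleles = [1] * b_ins + [0] * (2 - b_ins)
            if a_ins == 1 and b_ins != 1:
                pairs = [(1, b_alleles[0]), (0, b_alleles[1])]
            elif b_ins == 1 and a_ins != 1:
                pairs = [(a_alleles[0], 1), (a_alleles[1], 0)]
            else:
                pairs = list(zip(a_alleles, b_alleles))
            for ai, bi in pairs:
                base[3 - (2 * ai + bi)] += cnt
    # initialize at linkage equilibrium of the allele-count margins
    p1 = (2 * table[0].sum() + table[1].sum()) / (2 * n)
    p2 = (2 * table[:, 0].sum() + table[:, 1].sum()) / (2 * n)
    f = np.array(
        [p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)]
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    trace = [f.copy()]
    for _ in range(_EM_MAX_ITER):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        denom = coupling + repulsion
        w = coupling / denom if denom > 0 else 0.5
        counts = base.copy()
        counts[[0, 3]] += n_dh * w
        counts[[1, 2]] += n_dh * (1 - w)
        new = counts / (2 * n)
        trace.append(new.copy())
        if np.max(np.abs(new - f)) < _EM_TOL:
            f = new
            break
        f = new
    if return_trace:
        return f, trace
    return f


def hap_log_likelihood(table: np.ndarray, f: np.ndarray) -> float:
    """Observed-data log-likelihood of haplotype frequencies ``f``.

    The double-heterozygote cell mixes the two phase configurations.
    """
    table = np.asarray(table, dtype=float)
    f = np.clip(np.asarray(f, dtype=float), 1e-300, None)
    fII, fID, fDI, fDD = f
    # genotype-pair probabilities under random union of haplotypes
    probs = np.empty((3, 3))
    per_cell = {
        (0, 0): fII * fII,
        (0, 1): 2 * fII * fID,
        (0, 2): fID * fID,
        (1, 0): 2 * fII * fDI,
        (1, 1): 2 * fII * fDD + 2 * fID * fDI,
        (1, 2): 2 * fID * fDD,
        (2, 0): fDI * fDI,
        (2, 1): 2 * fDI * fDD,
        (2, 2): fDD * fDD,
    }
    for (i, j), pr in per_cell.items():
        probs[i, j] = pr
    with np.errstate(divide="ignore"):
        logp = np.where(table > 0, np.log(np.clip(probs, 1e-300, None)), 0.0)
    return float((table * logp).sum())


@dataclass
class LDPairResult:
    locus_pair: tuple[str, str]
    hap_freqs: np.ndarray  # I-I, I-D, D-I, D-D
    D: float | None
    D_prime: float | None
    r2: float | None
    above_threshold: bool

    @property
    def defined(self) -> bool:
        return self.r2 is not None


def ld_stats(hap_freqs: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies (I-I, I-D, D-I, D-D).

    Raises :class:`DegenerateInputError` if either locus is monomorphic.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    p1 = f[0] + f[1]
    p2 = f[0] + f[2]
    q1, q2 = 1.0 - p1, 1.0 - p2
    if min(p1, q1, p2, q2) <= 0.0:
        raise DegenerateInputError("LD undefined with a monomorphic locus")
    D = f[0] - p1 * p2
    if D >= 0:
        d_max = min(p1 * q2, q1 * p2)
    else:
        d_max = min(p1 * p2, q1 * q2)
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D * D / (p1 * q1 * p2 * q2)
    return float(D), float(d_prime), float(r2)


def ld_screen(gm: GenotypeMatrix, r2_threshold: float = 0.8) -> list[LDPairResult]:
    """EM-based LD statistics for every unordered locus pair.

    Pairs with a monomorphic locus are reported with undefined statistics
    and never counted against the threshold.
    """
    if gm.n_loci < 2:
        raise ValueError("need at least two loci")
    out = []
    for la, lb in combinations(gm.locus_ids, 2):
        table = pair_counts(gm, la, lb)
        f = em_haplotype_freqs(table)
        try:
            D, d_prime, r2 = ld_stats(f)
            above = r2 >= r2_threshold
        except DegenerateInputError:
            D = d_prime = r2 = None
            above = False
        out.append(LDPairResult((la, lb), f, D, d_prime, r2, above))
    return out
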