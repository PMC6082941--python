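"""Interpopulation differentiation: locus-by-locus tests, Nei's D_A
distance and Weir-Cockerham F_st, assembled into labelled matrices.

Nei's D_A between allele-frequency profiles x and y over L loci:

    D_A = 1 - (1/L) sum_l sum_alleles sqrt(x_la * y_la)

Weir-Cockerham theta is the 1984 variance-components estimator; the
multi-locus estimate is the ratio of summed "a" components to summed
(a + b + c) components across loci, which is stable when per-locus
variance is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .types import (
    MISSING,
    DegenerateInputError,
    DistanceMatrix,
    FreqTable,
    GenotypeMatrix,
)
from .equilibrium import bonferroni_threshold


# ---------------------------------------------------------------------------
# locus-by-locus differentiation tests
# ---------------------------------------------------------------------------

def allele_count_2x2(
    gm: GenotypeMatrix, pop_a: str, pop_b: str, locus: str
) -> np.ndarray:
    """2x2 allele-count table: rows = populations, cols = (insertion, deletion)."""
    from .forensic import locus_counts

    rows = []
    for pop in (pop_a, pop_b):
        c = locus_counts(gm.subset_population(pop), locus)
        rows.append([c.n_insertion, 2 * c.n - c.n_insertion])
    return np.asarray(rows, dtype=int)


def freq_table_2x2(
    ft: FreqTable, pop_a: str, pop_b: str, locus: str
) -> np.ndarray:
    """Allele-count table from a frequency table (requires sample sizes)."""
    if ft.sample_sizes is None:
        raise ValueError("frequency table carries no sample sizes")
    rows = []
    for pop in (pop_a, pop_b):
        n2 = int(2 * ft.sample_sizes[pop])
        ins = int(round(n2 * float(ft.freqs.loc[pop, locus])))
        rows.append([ins, n2 - ins])
    return np.asarray(rows, dtype=int)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 allele-count table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    if table.sum() == 0:
        raise DegenerateInputError("all-zero table")
    return float(_scipy_fisher(table, alternative="two-sided")[1])


def _theta_components_multi(geno: np.ndarray) -> tuple[float, float, float]:
    """(a, b, c) for one locus over r populations.

    ``geno`` is an (r, 3) array of (n_II, n_ID, n_DD) counts per population.
    """
    n_i = geno.sum(axis=1)
    if np.any(n_i < 1):
        raise DegenerateInputError("every population needs genotyped samples")
    r = geno.shape[0]
    p_i = (2 * geno[:, 0] + geno[:, 1]) / (2 * n_i)
    h_i = geno[:, 1] / n_i
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    if n_bar <= 1:
        raise DegenerateInputError("need more than one individual per population")
    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a), float(b), float(c)


def _pop_genotype_counts(gm: GenotypeMatrix, pops: list[str]) -> np.ndarray:
    """(n_pops, n_loci, 3) genotype-count array (II, ID, DD)."""
    out = np.zeros((len(pops), gm.n_loci, 3), dtype=float)
    for k, pop in enumerate(pops):
        sub = gm.subset_population(pop)
        out[k, :, 0] = (sub.calls == 2).sum(axis=0)
        out[k, :, 1] = (sub.calls == 1).sum(axis=0)
        out[k, :, 2] = (sub.calls == 0).sum(axis=0)
    return out


def wc_fst(gm: GenotypeMatrix, pops: list[str] | None = None) -> float:
    """Multi-locus Weir-Cockerham theta over the given populations.

    Computed as the ratio of summed variance components across loci.  May be
    slightly negative for undifferentiated populations; not clamped.
    """
    pops = list(pops) if pops is not None else gm.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    geno = _pop_genotype_counts(gm, pops)
    if np.any(geno.sum(axis=2).min(axis=0) < 2):
        raise DegenerateInputError("each population needs n >= 2 at every locus")
    num = den = 0.0
    for l in range(gm.n_loci):
        # monomorphic loci contribute nothing to either sum
        total_ins = (2 * geno[:, l, 0] + geno[:, l, 1]).sum()
        total_alleles = 2 * geno[:, l].sum()
        if total_ins == 0 or total_ins == total_alleles:
            continue
        a, b, c = _theta_components_multi(geno[:, l, :])
        num += a
        den += a + b + c
    if den == 0.0:
        raise DegenerateInputError("no polymorphic loci; theta undefined")
    return num / den


def locus_fst(gm: GenotypeMatrix, pops: list[str], locus: str) -> float:
    """Single-locus Weir-Cockerham theta (NaN if undefined)."""
    geno = _pop_genotype_counts(gm, pops)[:, gm.locus_index(locus), :]
    total_ins = (2 * geno[:, 0] + geno[:, 1]).sum()
    if total_ins == 0 or total_ins == 2 * geno.sum():
        return float("nan")
    a, b, c = _theta_components_multi(geno)
    den = a + b + c
    return a / den if den != 0 else float("nan")


def permutation_fst_test(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    locus: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for locus-wise theta between two populations.

    Individuals are shuffled between the two populations; the p-value is
    (1 + #{permuted theta >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation tests")
    rng = np.random.default_rng(seed)
    j = gm.locus_index(locus)
    calls_a = gm.subset_population(pop_a).calls[:, j]
    calls_b = gm.subset_population(pop_b).calls[:, j]
    pool = np.concatenate([calls_a, calls_b])
    na = len(calls_a)

    def theta_of(split_a: np.ndarray, split_b: np.ndarray) -> float:
        geno = np.array(
            [
                [(split_a == 2).sum(), (split_a == 1).sum(), (split_a == 0).sum()],
                [(split_b == 2).sum(), (split_b == 1).sum(), (split_b == 0).sum()],
            ],
            dtype=float,
        )
        total_ins = (2 * geno[:, 0] + geno[:, 1]).sum()
        if total_ins == 0 or total_ins == 2 * geno.sum():
            return float("nan")
        a, b, c = _theta_components_multi(geno)
        den = a + b + c
        return a / den if den != 0 else float("nan")

    observed = theta_of(calls_a, calls_b)
    if not np.isfinite(observed):
        return 1.0
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        t = theta_of(perm[:na], perm[na:])
        if np.isfinite(t) and t >= observed - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


@dataclass
class DifferentiationProfile:
    population_pair: tuple[str, str]
    p_values: pd.Series  # indexed by locus
    threshold: float

    @property
    def n_significant(self) -> int:
        return int((self.p_values < self.threshold).sum())


def differentiation_profile(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    alpha: float = 0.05,
    method: str = "fisher",
    n_perm: int = 1000,
    seed: int | None = None,
) -> DifferentiationProfile:
    """Locus-by-locus differentiation p-values between two populations.

    ``method`` is ``fisher`` (exact test on allele counts, the default for
    diallelic loci) or ``permutation`` (locus-wise theta permutation test).
    The significance threshold is Bonferroni-corrected to alpha / L.
    """
    pvals = {}
    for i, locus in enumerate(gm.locus_ids):
        if method == "fisher":
            pvals[locus] = fisher_exact_2x2(allele_count_2x2(gm, pop_a, pop_b, locus))
        elif method == "permutation":
            if seed is None:
                raise ValueError("permutation method requires a seed")
            pvals[locus] = permutation_fst_test(
                gm, pop_a, pop_b, locus, n_perm=n_perm, seed=seed + i
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    threshold = bonferroni_threshold(alpha, gm.n_loci)
    return DifferentiationProfile((pop_a, pop_b), pd.Series(pvals), threshold)


# ---------------------------------------------------------------------------
# genetic distances
# ---------------------------------------------------------------------------

def nei_da(freqs_x: np.ndarray, freqs_y: np.ndarray) -> float:
    """Nei's D_A distance between two insertion-frequency vectors.

    Each argument is the per-locus insertion frequency; the deletion
    frequency is its complement (diallelic loci).
    """
    x = np.asarray(freqs_x, dtype=float)
    y = np.asarray(freqs_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors cover different locus sets")
    if x.ndim != 1 or x.size == 0:
        raise ValueError("need a 1-D non-empty frequency vector")
    overlap = np.sqrt(x * y) + np.sqrt((1 - x) * (1 - y))
    return float(1.0 - overlap.mean())


def distance_matrix(
    source: GenotypeMatrix | FreqTable,
    metric: str = "da",
    clamp_negative: bool = True,
) -> DistanceMatrix:
    """Pairwise population distance matrix under ``metric`` (``da``/``fst``).

    Negative theta estimates are floored at zero in the matrix (the raw
    pairwise values are available via :func:`wc_fst`).
    """
    if metric == "da":
        ft = source if isinstance(source, FreqTable) else FreqTable.from_genotypes(source)
        pops = ft.population_ids
        vals = np.zeros((len(pops), len(pops)))
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                d = nei_da(ft.row(pops[i]), ft.row(pops[j]))
                vals[i, j] = vals[j, i] = max(d, 0.0)
        return DistanceMatrix(pops, vals)
    if metric == "fst":
        if not isinstance(source, GenotypeMatrix):
            raise ValueError("fst distances require genotype data")
        pops = source.populations
        vals = np.zeros((len(pops), len(pops)))
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                theta = wc_fst(source, [pops[i], pops[j]])
                if clamp_negative:
                    theta = max(theta, 0.0)
                vals[i, j] = vals[j, i] = theta
        return DistanceMatrix(pops, vals)
    raise ValueError(f"unknown metric {metric!r}")
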