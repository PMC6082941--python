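"""Synthetic genotype generators with the statistical structure the
analysis pipeline assumes: Hardy-Weinberg single populations (with
optional inbreeding), multi-population structure under the
Balding-Nichols model, admixed individuals, and locus pairs with
specified haplotype frequencies.

Every generator takes an explicit seed (no global RNG state) and is
bit-reproducible given its arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

# Published insertion-allele frequencies and sample size of the 30-locus
# Qiagen DIPplex autosomal InDel panel as typed in the Dongxiang population
# survey (n = 169); used as a realistic default panel for simulations.
DONGXIANG_N = 169
DONGXIANG_PANEL: dict[str, tuple[str, float]] = {
    "HLD 77": ("rs1611048", 0.4586),
    "HLD 45": ("rs2307959", 0.6746),
    "HLD 131": ("rs1611001", 0.4320),
    "HLD 70": ("rs2307652", 0.5680),
    "HLD 6": ("rs1610905", 0.4911),
    "HLD 111": ("rs1305047", 0.1598),
    "HLD 58": ("rs1610937", 0.3905),
    "HLD 56": ("rs2308292", 0.5799),
    "HLD 118": ("rs16438", 0.8550),
    "HLD 92": ("rs17174476", 0.3669),
    "HLD 93": ("rs2307570", 0.5473),
    "HLD 99": ("rs2308163", 0.8462),
    "HLD 88": ("rs8190570", 0.5266),
    "HLD 101": ("rs2307433", 0.4734),
    "HLD 67": ("rs1305056", 0.5651),
    "HLD 83": ("rs2308072", 0.3905),
    "HLD 114": ("rs2307581", 0.3077),
    "HLD 48": ("rs28369942", 0.3994),
    "HLD 124": ("rs6481", 0.5947),
    "HLD 122": ("rs8178524", 0.3254),
    "HLD 125": ("rs16388", 0.4527),
    "HLD 64": ("rs1610935", 0.7988),
    "HLD 81": ("rs17879936", 0.7633),
    "HLD 136": ("rs16363", 0.5148),
    "HLD 133": ("rs2067235", 0.3432),
    "HLD 97": ("rs17238892", 0.3669),
    "HLD 40": ("rs2307924", 0.6272),
    "HLD 128": ("rs17878444", 0.3728),
    "HLD 39": ("rs2307956", 0.2041),
    "HLD 84": ("rs3081400", 0.6746),
}


@dataclass
class SimSpec:
    """Bundled simulation settings (convenience; generators also take
    plain keyword arguments)."""

    n: int
    L: int
    seed: int
    allele_freqs: np.ndarray | None = None
    freq_range: tuple[float, float] = (0.1, 0.9)
    F_inbreeding: float = 0.0
    fst_target: float | None = None


def _resolve_freqs(
    L: int,
    allele_freqs: "np.ndarray | list[float] | None",
    freq_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    if allele_freqs is not None:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape != (L,):
            raise ValueError(f"expected {L} frequencies, got shape {p.shape}")
    else:
        p = rng.uniform(*freq_range, size=L)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return p


def _locus_names(L: int) -> list[str]:
    return [f"L{j + 1}" for j in range(L)]


def _draw_genotypes(
    p: np.ndarray, n: int, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n x L dosage calls with genotype probabilities
    (p^2 + Fpq, 2pq(1-F), q^2 + Fpq)."""
    q = 1.0 - p
    probs = np.stack(
        [q * q + F * p * q, 2 * p * q * (1 - F), p * p + F * p * q]
    )  # dosage 0, 1, 2
    u = rng.random((n, p.size))
    cum0 = probs[0]
    cum1 = probs[0] + probs[1]
    return ((u >= cum0).astype(np.int8) + (u >= cum1).astype(np.int8))


def simulate_hwe_population(
    n: int,
    L: int,
    seed: int,
    allele_freqs: "np.ndarray | list[float] | None" = None,
    freq_range: tuple[float, float] = (0.1, 0.9),
    F_inbreeding: float = 0.0,
    population: str = "pop_1",
    locus_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Single population of diallelic genotypes, HWE when F = 0."""
    if not 0.0 <= F_inbreeding <= 1.0:
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = _resolve_freqs(L, allele_freqs, freq_range, rng)
    calls = _draw_genotypes(p, n, F_inbreeding, rng)
    return GenotypeMatrix(
        [f"{population}_s{i + 1}" for i in range(n)],
        [population] * n,
        locus_ids or _locus_names(L),
        calls,
    )


def dongxiang_like_panel(seed: int, n: int = DONGXIANG_N) -> GenotypeMatrix:
    """HWE panel simulated at the published 30-locus insertion frequencies."""
    loci = list(DONGXIANG_PANEL)
    freqs = [DONGXIANG_PANEL[l][1] for l in loci]
    gm = simulate_hwe_population(
        n, len(loci), seed, allele_freqs=freqs, population="Dongxiang", locus_ids=loci
    )
    gm.rs_numbers = {l: DONGXIANG_PANEL[l][0] for l in loci}
    return gm


def simulate_balding_nichols(
    n_per_pop: "list[int] | int",
    L: int,
    fst: float,
    seed: int,
    n_pops: int | None = None,
    ancestral_freqs: "np.ndarray | list[float] | None" = None,
    freq_range: tuple[float, float] = (0.1, 0.9),
) -> GenotypeMatrix:
    """Multi-population genotypes under the Balding-Nichols model.

    Each population's locus frequency is drawn from
    Beta(p (1-c)/c, (1-p) (1-c)/c) with c = ``fst`` around the ancestral
    frequency p; genotypes are HWE within populations.  Loci whose Beta
    parameters would degenerate (ancestral p of 0 or 1) are redrawn from
    ``freq_range`` with a logged note.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie strictly between 0 and 1")
    if isinstance(n_per_pop, int):
        if n_pops is None:
            raise ValueError("give n_per_pop as a list, or set n_pops")
        sizes = [n_per_pop] * n_pops
    else:
        sizes = list(n_per_pop)
    if len(sizes) < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)
    p_anc = _resolve_freqs(L, ancestral_freqs, freq_range, rng)
    degenerate = (p_anc <= 0.0) | (p_anc >= 1.0)
    if degenerate.any():
        logger.info(
            "redrawing %d degenerate ancestral frequencies", int(degenerate.sum())
        )
        p_anc[degenerate] = rng.uniform(*freq_range, size=int(degenerate.sum()))
    scale = (1.0 - fst) / fst
    result: GenotypeMatrix | None = None
    for k, n in enumerate(sizes):
        p_pop = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
        calls = _draw_genotypes(p_pop, n, 0.0, rng)
        pop = f"pop_{k + 1}"
        gm = GenotypeMatrix(
            [f"{pop}_s{i + 1}" for i in range(n)],
            [pop] * n,
            _locus_names(L),
            calls,
        )
        result = gm if result is None else result.concat(gm)
    assert result is not None
    return result


def simulate_admixed(
    Q: np.ndarray,
    cluster_freqs: np.ndarray,
    seed: int,
    population: str = "admixed",
) -> GenotypeMatrix:
    """Admixed individuals: each allele copy picks a cluster by its row of
    ``Q`` then an allele from that cluster's insertion frequency."""
    Q = np.asarray(Q, dtype=float)
    cluster_freqs = np.asarray(cluster_freqs, dtype=float)
    if Q.ndim != 2 or cluster_freqs.ndim != 2 or Q.shape[1] != cluster_freqs.shape[0]:
        raise ValueError("Q is (n, K) and cluster_freqs is (K, L)")
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of Q must sum to 1")
    rng = np.random.default_rng(seed)
    n, K = Q.shape
    L = cluster_freqs.shape[1]
    calls = np.zeros((n, L), dtype=np.int8)
    for c in range(2):
        # cluster choice is per allele copy and per locus
        z = (rng.random((n, L, 1)) > np.cumsum(Q, axis=1)[:, None, :]).sum(axis=2)
        p = cluster_freqs[z, np.arange(L)[None, :]]
        calls += (rng.random((n, L)) < p).astype(np.int8)
    return GenotypeMatrix(
        [f"{population}_s{i + 1}" for i in range(n)],
        [population] * n,
        _locus_names(L),
        calls,
    )


def simulate_ld_pair(
    hap_freqs: "np.ndarray | list[float]", n: int, seed: int
) -> GenotypeMatrix:
    """Two-locus genotypes from haplotype frequencies (I-I, I-D, D-I, D-D).

    2n haplotypes are drawn i.i.d. and paired randomly into unphased
    genotypes.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("need 4 non-negative haplotype frequencies summing to 1")
    rng = np.random.default_rng(seed)
    haps = rng.choice(4, size=2 * n, p=f)
    # haplotype codes: 0 = I-I, 1 = I-D, 2 = D-I, 3 = D-D
    a_allele = (haps < 2).astype(np.int8)  # insertion at locus A
    b_allele = (haps % 2 == 0).astype(np.int8)  # insertion at locus B
    calls = np.stack(
        [
            a_allele[:n] + a_allele[n:],
            b_allele[:n] + b_allele[n:],
        ],
        axis=1,
    )
    return GenotypeMatrix(
        [f"s{i + 1}" for i in range(n)],
        ["pop_1"] * n,
        ["locus_A", "locus_B"],
        calls,
    )
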