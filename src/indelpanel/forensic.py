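"""Per-locus forensic efficiency statistics for diallelic InDel loci and
their panel-wide combinations.

For a locus with genotype counts (n_II, n_ID, n_DD), n individuals and
insertion frequency p = (2 n_II + n_ID) / 2n:

* match probability        MP  = sum over genotype classes of (count/n)^2
  (observed genotype frequencies, not Hardy-Weinberg expectations)
* discrimination power     DP  = 1 - MP
* polymorphism information PIC = 1 - (p^2 + q^2) - 2 p^2 q^2
* observed heterozygosity  Ho  = n_ID / n
* expected heterozygosity  He  = 2n/(2n-1) * 2pq   (Nei's unbiased form)
* power of exclusion       PE  = Ho^2 (1 - 2 Ho (1-Ho)^2)
* typing paternity index   TPI = 1 / (2 (1 - Ho))

A panel combines loci under the assumption of independence:
CMP = prod MP_l and CPE = 1 - prod (1 - PE_l), accumulated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    DD,
    ID,
    II,
    DegenerateInputError,
    GenotypeMatrix,
    LocusCounts,
)


def locus_counts(gm: GenotypeMatrix, locus: str) -> LocusCounts:
    """Genotype counts at ``locus`` over non-missing calls."""
    col = gm.calls[:, gm.locus_index(locus)]
    return LocusCounts(
        int(np.sum(col == II)), int(np.sum(col == ID)), int(np.sum(col == DD))
    )


def insertion_freq(c: LocusCounts) -> float:
    """Insertion-allele frequency p = (2 n_II + n_ID) / 2n."""
    if c.n == 0:
        raise DegenerateInputError("no non-missing genotypes at locus")
    return c.n_insertion / (2.0 * c.n)


def observed_het(c: LocusCounts) -> float:
    """Observed heterozygosity Ho = n_ID / n."""
    if c.n == 0:
        raise DegenerateInputError("no non-missing genotypes at locus")
    return c.n_ID / c.n


def expected_het_unbiased(p: float, n: int) -> float:
    """Nei's unbiased expected heterozygosity, 2n/(2n-1) * 2pq."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    if n < 1:
        raise DegenerateInputError("need at least one individual")
    return (2 * n) / (2 * n - 1) * (1.0 - p * p - (1.0 - p) ** 2)


def pic(p: float) -> float:
    """Polymorphism information content for a diallelic locus."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def match_probability(c: LocusCounts) -> float:
    """Probability that two random individuals share a genotype.

    Uses observed genotype class frequencies, the convention of forensic
    summary spreadsheets (PowerStats-style), not HWE expectations.
    """
    if c.n == 0:
        raise DegenerateInputError("no non-missing genotypes at locus")
    n = float(c.n)
    return (c.n_II / n) ** 2 + (c.n_ID / n) ** 2 + (c.n_DD / n) ** 2


def power_exclusion(ho: float) -> float:
    """Power of exclusion from observed heterozygosity (single-parent form)."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"heterozygosity {ho} outside [0, 1]")
    hom = 1.0 - ho
    return ho * ho * (1.0 - 2.0 * ho * hom * hom)


def typing_paternity_index(ho: float) -> float:
    """TPI = 1 / (2 (1 - Ho)); infinite at Ho = 1 is signalled as an error."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"heterozygosity {ho} outside [0, 1]")
    if ho == 1.0:
        raise DegenerateInputError("TPI undefined (infinite) at Ho = 1")
    return 1.0 / (2.0 * (1.0 - ho))


def reconstruct_counts(p: float, tpi: float, n: int) -> LocusCounts:
    """Invert (insertion frequency, TPI, n) to integer genotype counts.

    Useful for recovering genotype counts from published per-locus summary
    rows.  Raises if the rounded counts are not integer-consistent.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly between 0 and 1")
    if tpi < 0.5:
        raise ValueError("TPI below its diallelic minimum of 0.5")
    n_ins = round(2 * n * p)
    n_id = round(n * (1.0 - 1.0 / (2.0 * tpi)))
    if (n_ins - n_id) % 2:
        raise ValueError(
            f"inconsistent summary: {n_ins} insertion copies with {n_id} "
            "heterozygotes leaves an odd homozygote copy count"
        )
    n_ii = (n_ins - n_id) // 2
    n_dd = n - n_ii - n_id
    counts = LocusCounts(n_ii, n_id, n_dd)
    if min(counts) < 0:
        raise ValueError(f"inconsistent summary: negative count in {counts}")
    return counts


def combined_panel_stats(
    mp_values: "np.ndarray | list[float]", pe_values: "np.ndarray | list[float]"
) -> tuple[float, float]:
    """Panel-wide CMP and CPE, accumulated in log space.

    CMP = prod(MP_l); CPE = 1 - prod(1 - PE_l).
    """
    mp_arr = np.asarray(mp_values, dtype=float)
    pe_arr = np.asarray(pe_values, dtype=float)
    if mp_arr.size == 0 or pe_arr.size == 0:
        raise DegenerateInputError("need at least one locus")
    bad = np.flatnonzero(~np.isfinite(mp_arr) | ~np.isfinite(pe_arr))
    if bad.size:
        raise ValueError(f"missing per-locus statistic at indices {bad.tolist()}")
    cmp_ = math.exp(float(np.log(mp_arr).sum())) if np.all(mp_arr > 0) else 0.0
    if np.any(pe_arr >= 1.0):
        cpe = 1.0
    else:
        cpe = -math.expm1(float(np.log1p(-pe_arr).sum()))
    return cmp_, cpe


@dataclass
class ForensicProfile:
    """Per-locus summary table plus panel-wide combinations.

    ``table`` has one row per locus with columns locus, rs, n, p_ins, p_del,
    MP, DP, PIC, PE, TPI, Ho, He, hwe_p.
    """

    table: pd.DataFrame
    cmp: float
    cpe: float

    @property
    def log10_cmp(self) -> float:
        return float(np.log10(self.table["MP"]).sum())

    @property
    def log10_one_minus_cpe(self) -> float:
        return float(np.log1p(-self.table["PE"]).sum() / math.log(10))


def profile_table(gm: GenotypeMatrix) -> ForensicProfile:
    """Full per-locus forensic summary for every locus in ``gm``."""
    from .equilibrium import hwe_exact  # local import to avoid a cycle

    rows = []
    for locus in gm.locus_ids:
        c = locus_counts(gm, locus)
        if c.n == 0:
            raise DegenerateInputError(f"locus {locus!r} has no non-missing calls")
        p = insertion_freq(c)
        ho = observed_het(c)
        mp = match_probability(c)
        rows.append(
            {
                "locus": locus,
                "rs": gm.rs_numbers.get(locus, ""),
                "n": c.n,
                "p_ins": p,
                "p_del": 1.0 - p,
                "MP": mp,
                "DP": 1.0 - mp,
                "PIC": pic(p),
                "PE": power_exclusion(ho),
                "TPI": typing_paternity_index(ho) if ho < 1 else math.inf,
                "Ho": ho,
                "He": expected_het_unbiased(p, c.n),
                "hwe_p": hwe_exact(c),
            }
        )
    table = pd.DataFrame(rows)
    cmp_, cpe = combined_panel_stats(table["MP"].to_numpy(), table["PE"].to_numpy())
    return ForensicProfile(table, cmp_, cpe)
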