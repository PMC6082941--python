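"""Readers and writers for genotype tables, frequency tables, distance
matrices and trees.

Supported dialects
------------------
* CSV/TSV genotype tables: header row names the loci; the first two columns
  are sample id and population label; cells are II / ID / DD / MISSING.
* GenePop: two-digit allele codes with 01 = insertion, 02 = deletion,
  00 = missing; comma after the sample name; ``POP`` lines separate
  populations (the dialect of Genepop 4.x input files).
* PHYLIP square distance matrix (leading taxon count, 10-character name
  field).
* Newick trees, delegated to scikit-bio.

All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .types import (
    DD,
    ID,
    II,
    MISSING,
    CODE_TO_STR,
    STR_TO_CODE,
    FreqTable,
    GenotypeMatrix,
    DistanceMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

_GENEPOP_ALLELE = {"01": 1, "02": 0}  # insertion dosage contribution
_ALLELE_TO_GENEPOP = {II: "0101", ID: "0102", DD: "0202", MISSING: "0000"}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path, dialect: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the given dialect.

    ``dialect`` is one of ``csv``, ``tsv`` or ``genepop``.
    """
    path = Path(path)
    if dialect in ("csv", "tsv"):
        return _read_delimited(path, sep="," if dialect == "csv" else "\t")
    if dialect == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotype_table(
    gm: GenotypeMatrix, path: str | Path, dialect: str = "csv"
) -> None:
    path = Path(path)
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        lines = [sep.join(["sample_id", "population", *gm.locus_ids])]
        for i, sid in enumerate(gm.sample_ids):
            cells = [CODE_TO_STR[int(c)] for c in gm.calls[i]]
            lines.append(sep.join([sid, gm.population_labels[i], *cells]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    elif dialect == "genepop":
        _write_genepop(gm, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_delimited(path: Path, sep: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need sample id and population columns")
    locus_ids = list(df.columns[2:])
    sample_ids = df.iloc[:, 0].tolist()
    pops = df.iloc[:, 1].tolist()
    calls = np.empty((len(sample_ids), len(locus_ids)), dtype=np.int8)
    for j, locus in enumerate(locus_ids):
        for i, cell in enumerate(df.iloc[:, 2 + j]):
            code = STR_TO_CODE.get(cell.strip())
            if code is None:
                raise ParseError(
                    f"{path}, line {i + 2}: unknown genotype code {cell!r} "
                    f"at locus {locus!r}"
                )
            calls[i, j] = code
    return GenotypeMatrix(sample_ids, pops, locus_ids, calls)


def _read_genepop(path: Path) -> GenotypeMatrix:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    # line 0 is a title; locus names follow, one per line or comma-separated
    cursor = 1
    locus_ids: list[str] = []
    while cursor < len(lines) and lines[cursor].strip().upper() != "POP":
        chunk = [t.strip() for t in lines[cursor].split(",") if t.strip()]
        locus_ids.extend(chunk)
        cursor += 1
    sample_ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_counter = 0
    for lineno in range(cursor, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if raw.strip().upper() == "POP":
            pop_counter += 1
            continue
        if "," not in raw:
            raise ParseError(f"{path}, line {lineno + 1}: missing comma after sample name")
        name, _, geno = raw.partition(",")
        codes = geno.split()
        if len(codes) != len(locus_ids):
            raise ParseError(
                f"{path}, line {lineno + 1}: expected {len(locus_ids)} genotypes, "
                f"got {len(codes)}"
            )
        row = []
        for locus, code in zip(locus_ids, codes):
            if len(code) != 4 or not code.isdigit():
                raise ParseError(
                    f"{path}, line {lineno + 1}: malformed genotype {code!r} at {locus!r}"
                )
            a, b = code[:2], code[2:]
            if a == "00" or b == "00":
                row.append(MISSING)
                continue
            if a not in _GENEPOP_ALLELE or b not in _GENEPOP_ALLELE:
                raise ParseError(
                    f"{path}, line {lineno + 1}: unknown allele code in {code!r} "
                    f"at {locus!r} (expected 00/01/02)"
                )
            row.append(_GENEPOP_ALLELE[a] + _GENEPOP_ALLELE[b])
        sample_ids.append(name.strip())
        pops.append(f"pop_{pop_counter}")
        rows.append(row)
    calls = (
        np.asarray(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(locus_ids)), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, pops, locus_ids, calls)


def _write_genepop(gm: GenotypeMatrix, path: Path) -> None:
    lines = ["indelpanel genotype export"]
    lines.extend(gm.locus_ids)
    current = object()
    for i, sid in enumerate(gm.sample_ids):
        if gm.population_labels[i] != current:
            current = gm.population_labels[i]
            lines.append("POP")
        cells = " ".join(_ALLELE_TO_GENEPOP[int(c)] for c in gm.calls[i])
        lines.append(f"{sid} , {cells}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------

def read_freq_table(path: str | Path, sep: str = "\t") -> FreqTable:
    """Read a population x locus insertion-frequency table.

    An optional ``n`` column carries per-population sample sizes.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    sizes = None
    if "n" in df.columns:
        sizes = df.pop("n").astype(int)
    vals = df.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        bad = df.columns[np.argwhere((vals < 0) | (vals > 1))[0][1]]
        raise ValidationError(f"{path}: frequency outside [0, 1] at locus {bad!r}")
    return FreqTable(df, sizes)


def write_freq_table(ft: FreqTable, path: str | Path, sep: str = "\t") -> None:
    df = ft.freqs.round(6).copy()
    if ft.sample_sizes is not None:
        df.insert(0, "n", ft.sample_sizes.astype(int))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep=sep, index_label="population")


# ---------------------------------------------------------------------------
# PHYLIP distance matrices and Newick trees
# ---------------------------------------------------------------------------

_PHYLIP_NAME_WIDTH = 10


def _phylip_names(labels: list[str]) -> list[str]:
    """Truncate labels to the PHYLIP name field, disambiguating clashes."""
    out: list[str] = []
    seen: dict[str, int] = {}
    for lab in labels:
        name = lab[:_PHYLIP_NAME_WIDTH]
        if len(lab) > _PHYLIP_NAME_WIDTH:
            logger.warning("label %r truncated to %r for PHYLIP output", lab, name)
        if name in seen:
            seen[name] += 1
            suffix = str(seen[name])
            name = name[: _PHYLIP_NAME_WIDTH - len(suffix)] + suffix
            logger.warning("duplicate PHYLIP name disambiguated as %r", name)
        else:
            seen[name] = 0
        out.append(name)
    return out


def write_phylip_distance(dm: DistanceMatrix, path: str | Path) -> None:
    names = _phylip_names(dm.labels)
    lines = [f"{dm.size}"]
    for i, name in enumerate(names):
        row = " ".join(f"{v:.6f}" for v in dm.values[i])
        lines.append(f"{name:<{_PHYLIP_NAME_WIDTH}} {row}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_phylip_distance(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    k = int(lines[0].strip())
    labels, rows = [], []
    for line in lines[1 : k + 1]:
        name = line[:_PHYLIP_NAME_WIDTH].strip()
        vals = [float(v) for v in line[_PHYLIP_NAME_WIDTH:].split()]
        labels.append(name)
        rows.append(vals)
    return DistanceMatrix(labels, np.asarray(rows))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
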