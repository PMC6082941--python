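"""End-to-end orchestration of the panel analysis workflow.

Stages run in dependency order: forensic summary -> HWE/LD screens ->
differentiation and distance matrices -> tree/MDS -> admixture.  Every
stage writes plain-text outputs into the run directory and the whole run
is described by a machine-readable JSON manifest (inputs, parameters,
seeds, per-stage outputs, wall-clock).  Reruns with identical config and
seeds produce byte-identical stochastic outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import GenotypeMatrix
from . import io as panel_io
from .forensic import profile_table
from .equilibrium import hwe_screen, ld_screen, bonferroni_threshold
from .divergence import differentiation_profile, distance_matrix
from .topology import neighbor_joining, classical_mds, MDSConfig
from .admixture import structure_fit

logger = logging.getLogger(__name__)

STAGES = ("summary", "hwe", "ld", "diff", "distance", "tree", "mds", "structure")


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`."""

    genotypes: str
    out_dir: str
    dialect: str = "csv"
    stages: tuple[str, ...] = STAGES
    alpha: float = 0.05
    r2_threshold: float = 0.8
    distance_metric: str = "da"
    k_range: tuple[int, ...] = tuple(range(2, 8))
    burn_in: int = 10_000
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2 threshold must be in (0, 1]")


def write_profile_tsv(profile, path: Path) -> None:
    """Table-shaped per-locus forensic summary with a CMP/CPE footer."""
    table = profile.table.copy()
    stat_cols = [c for c in table.columns if c not in ("locus", "rs", "n")]
    table[stat_cols] = table[stat_cols].round(4)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        table.to_csv(fh, sep="\t", index=False)
        fh.write(f"# CMP\t{profile.cmp:.6e}\n")
        fh.write(f"# CPE\t{profile.cpe:.6f}\n")


def run_pipeline(cfg: RunConfig, gm: GenotypeMatrix | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if gm is None:
        gm = panel_io.read_genotype_table(cfg.genotypes, cfg.dialect)
    logger.info(
        "run: alpha=%s r2_threshold=%s seed=%s stages=%s",
        cfg.alpha,
        cfg.r2_threshold,
        cfg.seed,
        ",".join(cfg.stages),
    )
    manifest: dict = {
        "version": __version__,
        "inputs": {"genotypes": str(cfg.genotypes), "dialect": cfg.dialect},
        "parameters": {
            "alpha": cfg.alpha,
            "r2_threshold": cfg.r2_threshold,
            "distance_metric": cfg.distance_metric,
            "k_range": list(cfg.k_range),
            "burn_in": cfg.burn_in,
            "reps": cfg.reps,
            "seed": cfg.seed,
        },
        "stages": {},
    }

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = [str(f.relative_to(out)) for f in files]

    try:
        if "summary" in cfg.stages:
            prof = profile_table(gm)
            f = out / "summary.tsv"
            write_profile_tsv(prof, f)
            record("summary", [f])
        if "hwe" in cfg.stages:
            res = hwe_screen(gm, cfg.alpha)
            df = pd.DataFrame(
                [
                    {
                        "locus": r.locus_id,
                        "p_exact": r.p_exact,
                        "p_chi2": r.p_chi2,
                        "chi2": r.chi2,
                        "significant": r.significant_after_bonferroni,
                    }
                    for r in res
                ]
            )
            f = out / "hwe.tsv"
            _write_tsv(df, f)
            record("hwe", [f])
        if "ld" in cfg.stages:
            res = ld_screen(gm, cfg.r2_threshold)
            df = pd.DataFrame(
                [
                    {
                        "locus_a": r.locus_pair[0],
                        "locus_b": r.locus_pair[1],
                        "f_II": r.hap_freqs[0],
                        "f_ID": r.hap_freqs[1],
                        "f_DI": r.hap_freqs[2],
                        "f_DD": r.hap_freqs[3],
                        "D": r.D,
                        "D_prime": r.D_prime,
                        "r2": r.r2,
                        "above_threshold": r.above_threshold,
                    }
                    for r in res
                ]
            )
            f = out / "ld_pairs.tsv"
            _write_tsv(df, f)
            record("ld", [f])
        pops = gm.populations
        if "diff" in cfg.stages and len(pops) >= 2:
            rows = []
            for i in range(len(pops)):
                for j in range(i + 1, len(pops)):
                    prof = differentiation_profile(gm, pops[i], pops[j], cfg.alpha)
                    rows.append(
                        {
                            "pop_a": pops[i],
                            "pop_b": pops[j],
                            "n_significant": prof.n_significant,
                            "threshold": prof.threshold,
                        }
                    )
            f = out / "differentiation.tsv"
            _write_tsv(pd.DataFrame(rows), f)
            record("diff", [f])
        dm = None
        if ("distance" in cfg.stages or "tree" in cfg.stages or "mds" in cfg.stages) and len(pops) >= 2:
            dm = distance_matrix(gm, cfg.distance_metric)
        if "distance" in cfg.stages and dm is not None:
            f_tsv = out / f"distance_{cfg.distance_metric}.tsv"
            f_phy = out / f"distance_{cfg.distance_metric}.phylip"
            _write_tsv(dm.to_frame(), f_tsv, index=True)
            panel_io.write_phylip_distance(dm, f_phy)
            record("distance", [f_tsv, f_phy])
        if "tree" in cfg.stages and dm is not None and dm.size >= 3:
            tree = neighbor_joining(dm)
            f = out / "tree.nwk"
            panel_io.write_newick(tree, f)
            record("tree", [f])
        if "mds" in cfg.stages and dm is not None:
            res = classical_mds(dm, MDSConfig(n_dims=min(2, dm.size - 1)))
            f = out / "mds_coords.tsv"
            _write_tsv(res.coordinates, f, index=True)
            record("mds", [f])
        if "structure" in cfg.stages:
            files = []
            for k in cfg.k_range:
                fit = structure_fit(
                    gm,
                    K=k,
                    burn_in=cfg.burn_in,
                    reps=cfg.reps,
                    seed=cfg.seed + k,
                )
                f = out / f"q_matrix_K{k}.tsv"
                _write_tsv(fit.Q.to_frame(), f, index=True)
                files.append(f)
            record("structure", files)
    except Exception as exc:
        manifest["failed_stage"] = _current_stage(manifest)
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
        )
        raise
    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest


def _current_stage(manifest: dict) -> str:
    done = set(manifest["stages"])
    for stage in STAGES:
        if stage not in done:
            return stage
    return "unknown"


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index)
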