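"""End-to-end inference chain: inputs -> TF activities -> skip calls -> ILP
solution pool -> consensus network, with all artifacts written to disk."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .ilp import IlpParams, build_ilp, validate_solution, write_solution
from .pool import consensus, enumerate_solutions, write_consensus
from .prior import attach_perturbation, build_network, load_interaction_table
from .splice import SKIP_COLUMNS, call_skipped_domains, load_evidence, write_skip_table
from .tf import load_gene_stats, load_regulons, permutation_significance, write_tf_table

logger = logging.getLogger(__name__)


def empty_skip_table() -> pd.DataFrame:
    return pd.DataFrame(columns=SKIP_COLUMNS)


def infer_pool(net, tf_table, skips, cfg: RunConfig, mode: str | None = None):
    """Build the ILP from prepared tables and enumerate the solution pool."""
    params = IlpParams(alpha=cfg.alpha, lam=cfg.lam, beta=cfg.beta)
    instance = build_ilp(net, tf_table, skips, mode=mode or cfg.mode, params=params)
    pool = enumerate_solutions(
        instance,
        k_max=cfg.k_max,
        objective_tolerance=cfg.tolerance,
        backend=cfg.backend,
        time_limit=cfg.time_limit_s,
        mip_gap=cfg.mip_gap,
    )
    for i, sol in enumerate(pool):
        violations = validate_solution(net, skips, sol)
        if violations:
            raise RuntimeError(f"solution {i} failed certification: {violations[:3]}")
    return instance, pool


def run(cfg: RunConfig, mode: str | None = None) -> Path:
    """Execute the full chain described by a config; returns the output dir."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("splicewire")
    root_logger.addHandler(log_handler)
    try:
        mode = mode or cfg.mode
        logger.info("run start: mode=%s seed=%d backend=%s", mode, cfg.seed, cfg.backend)
        records = load_interaction_table(cfg.interactions)
        regulons = load_regulons(cfg.regulons)
        gene_stats = load_gene_stats(cfg.gene_stats)
        net = build_network(records)
        attach_perturbation(net, roots=cfg.roots, tfs={r.tf for r in regulons})
        tf_table = permutation_significance(
            regulons, gene_stats, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.p_tf
        )
        write_tf_table(tf_table, outdir / "tf_activity.tsv")
        if cfg.evidence is not None:
            evidence = load_evidence(cfg.evidence)
            skips = call_skipped_domains(net, evidence, p_threshold=cfg.p_skip)
        else:
            logger.info("no splice evidence configured: splice-unaware run")
            skips = empty_skip_table()
        write_skip_table(skips, outdir / "domain_skips.tsv")
        _, pool = infer_pool(net, tf_table, skips, cfg, mode=mode)
        for i, sol in enumerate(pool):
            write_solution(sol, outdir / f"solution_{i}.tsv")
        cn = consensus(pool)
        write_consensus(cn, outdir / "consensus.tsv", outdir / "consensus_nodes.tsv", skips=skips)
        cfg_out = RunConfig(**{**cfg.__dict__, "mode": mode})
        cfg_out.to_yaml(outdir / "resolved_config.yaml")
        logger.info(
            "run done: %d solutions, consensus of %d DDIs, objective %.6g",
            len(pool), len(cn.ddi_counts), pool[0].objective_value if pool else 0.0,
        )
        return outdir
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()
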