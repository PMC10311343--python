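"""Transcription-factor activity scores with a permutation null.

A TF's activity is the signed, sqrt(k)-normalized mean of its regulon targets'
differential expression statistics (mode +1 for activated targets, -1 for
repressed ones). Significance comes from randomizing the bipartite TF-to-target
graph: targets are resampled without replacement from the pooled target
universe, preserving each TF's out-degree and keeping the regulation modes; the
empirical p-value is the two-sided, add-one-smoothed tail probability of the
observed score under that null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prior import InputError

logger = logging.getLogger(__name__)

TF_COLUMNS = ["tf", "score", "empirical_p", "significant", "weight"]

#: regulon confidence classes used by default when a confidence column exists
DEFAULT_CONFIDENCE = ("A", "B", "C")


@dataclass(frozen=True)
class Regulon:
    """A TF with its target genes and regulation modes (+1 / -1)."""

    tf: str
    targets: tuple[tuple[str, int], ...]
    confidence: str | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise InputError(f"regulon {self.tf} has no targets")
        genes = [g for g, _ in self.targets]
        if len(genes) != len(set(genes)):
            raise InputError(f"regulon {self.tf} has duplicate target genes")


def load_regulons(path, confidence_filter=DEFAULT_CONFIDENCE) -> list[Regulon]:
    """Read a regulon TSV with headers tf, target, mode[, confidence].

    Unknown/missing modes default to +1. When a confidence column exists,
    rows outside ``confidence_filter`` are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    for col in ("tf", "target"):
        if col not in df.columns:
            raise InputError(f"regulon file {path} missing column {col!r}")
    if "confidence" in df.columns and confidence_filter is not None:
        df = df[df["confidence"].isin(confidence_filter)]
    regs = []
    for tf, grp in df.groupby("tf", sort=True):
        targets = []
        seen = set()
        for r in grp.itertuples(index=False):
            if r.target in seen:
                continue
            seen.add(r.target)
            mode = getattr(r, "mode", 1)
            try:
                mode = int(mode)
            except (TypeError, ValueError):
                mode = 1
            targets.append((str(r.target), 1 if mode >= 0 else -1))
        conf = None
        if "confidence" in df.columns:
            uniq = set(grp["confidence"])
            conf = uniq.pop() if len(uniq) == 1 else None
        regs.append(Regulon(tf=str(tf), targets=tuple(targets), confidence=conf))
    if not regs:
        raise InputError(f"no regulons loaded from {path}")
    return regs


def score_tf(regulon: Regulon, gene_stats) -> float | None:
    """Signed sqrt(k)-normalized regulon enrichment score.

    score = (1/sqrt(k)) * sum over matched targets of mode * stat(target),
    with k the number of regulon targets present in ``gene_stats``. Returns
    None (with a warning) when no target matches.
    """
    matched = [(g, m) for g, m in regulon.targets if g in gene_stats]
    if not matched:
        logger.warning("regulon %s has no target with an expression statistic", regulon.tf)
        return None
    total = sum(m * gene_stats[g] for g, m in matched)
    return float(total / math.sqrt(len(matched)))


def permutation_significance(
    regulons,
    gene_stats,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    scheme: str = "degree",
) -> pd.DataFrame:
    """Score every regulon and assign an empirical two-sided p-value.

    The null preserves each TF's out-degree: per permutation, the matched
    targets are resampled without replacement from the union of all regulon
    targets that carry an expression statistic, keeping the original modes
    (``scheme='degree'``). ``scheme='global'`` instead permutes the statistic
    values across that target universe once per permutation.

    empirical_p = (1 + #{|score_perm| >= |score_obs|}) / (n_perm + 1); the
    add-one smoothing keeps p-values strictly positive. TFs whose regulon has
    no matched target are omitted.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if scheme not in ("degree", "global"):
        raise InputError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)

    universe = sorted({g for reg in regulons for g, _ in reg.targets if g in gene_stats})
    stats_vec = np.asarray([gene_stats[g] for g in universe], dtype=float)
    n_universe = len(universe)

    rows = []
    for reg in sorted(regulons, key=lambda r: r.tf):
        matched = [(g, m) for g, m in reg.targets if g in gene_stats]
        if not matched:
            logger.warning("omitting TF %s: no matched targets", reg.tf)
            continue
        k = len(matched)
        if k > n_universe:
            raise InputError(
                f"regulon {reg.tf} ({k} matched targets) exceeds the target universe ({n_universe})"
            )
        modes = np.asarray([m for _, m in matched], dtype=float)
        obs = float(np.dot(modes, [gene_stats[g] for g, _ in matched]) / math.sqrt(k))

        null = np.empty(n_perm)
        for i in range(n_perm):
            if scheme == "degree":
                idx = rng.choice(n_universe, size=k, replace=False)
                null[i] = float(np.dot(modes, stats_vec[idx]) / math.sqrt(k))
            else:  # global: shuffle statistics over the universe
                perm = rng.permutation(n_universe)
                lookup = dict(zip(universe, stats_vec[perm]))
                null[i] = float(
                    np.dot(modes, [lookup[g] for g, _ in matched]) / math.sqrt(k)
                )
        # tolerance absorbs summation-order jitter so exact-tie nulls count
        tol = 1e-9 * max(1.0, abs(obs))
        n_extreme = int(np.sum(np.abs(null) >= abs(obs) - tol))
        emp_p = (1.0 + n_extreme) / (n_perm + 1.0)
        rows.append(
            {
                "tf": reg.tf,
                "score": obs,
                "empirical_p": emp_p,
                "significant": emp_p <= alpha,
                "weight": abs(obs),
            }
        )
    return pd.DataFrame(rows, columns=TF_COLUMNS)


def load_gene_stats(path) -> dict[str, float]:
    """Read a gene statistics TSV with headers gene, stat."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "stat"):
        if col not in df.columns:
            raise InputError(f"gene stats file {path} missing column {col!r}")
    return {str(r.gene): float(r.stat) for r in df.itertuples(index=False)}


def write_tf_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_tf_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TF_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"TF table {path} missing columns {sorted(missing)}")
    return df[TF_COLUMNS]
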