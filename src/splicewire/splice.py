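"""Per-domain skip calls from differential splicing / transcript evidence.

Exon-skipping statistics (dPSI with a p-value per exon) and differential
transcript abundance (logFC with a p-value per transcript) are mapped onto the
protein domains they encode. Per domain, the matched p-values are combined by
Fisher's method and the matched effects averaged; a domain is called *skipped*
when the combined p-value passes the threshold and the mean effect is negative
(exon exclusion / reduced transcript abundance — an included exon cannot remove
a domain).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .prior import InputError, PriorNetwork

logger = logging.getLogger(__name__)

#: smallest admissible p-value before taking logs
P_FLOOR = 1e-300

SKIP_COLUMNS = ["protein", "domain", "aggregated_p", "mean_effect", "n_features", "skipped"]


@dataclass(frozen=True)
class FeatureEvidence:
    """Differential statistic for one exon or transcript.

    ``effect`` is dPSI for exons (clipped to [-1, 1]) or log2 fold change for
    transcripts; negative values indicate exclusion / reduced abundance.
    """

    feature_id: str
    effect: float
    p_value: float
    feature_kind: str = "exon"

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise InputError("feature_id must be non-empty")
        if self.feature_kind not in ("exon", "transcript"):
            raise InputError(f"feature_kind must be exon|transcript, got {self.feature_kind!r}")
        if not (0.0 < self.p_value <= 1.0):
            raise InputError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.feature_kind == "exon" and abs(self.effect) > 1.0:
            # dPSI is a difference of proportions; clip rather than reject
            object.__setattr__(self, "effect", max(-1.0, min(1.0, self.effect)))


def fisher_aggregate(p_values) -> float:
    """Combine p-values by Fisher's method.

    Returns the survival probability of X = -2 * sum(ln p_i) under a
    chi-square distribution with 2k degrees of freedom. With a single p-value
    this is the identity.
    """
    p_values = list(p_values)
    if not p_values:
        raise InputError("fisher_aggregate requires at least one p-value")
    if any(p <= 0 or p > 1 for p in p_values):
        raise InputError("p-values must lie in (0, 1]")
    x = -2.0 * sum(math.log(max(p, P_FLOOR)) for p in p_values)
    return float(stats.chi2.sf(x, df=2 * len(p_values)))


def mean_effect(effects) -> float:
    """Arithmetic mean of the matched effect sizes (dPSI / logFC)."""
    effects = list(effects)
    if not effects:
        raise InputError("mean_effect requires at least one value")
    return float(sum(effects) / len(effects))


def call_skipped_domains(
    net: PriorNetwork,
    evidence,
    p_threshold: float = 0.05,
    strict_all_features: bool = False,
) -> pd.DataFrame:
    """Aggregate feature evidence into a per-domain skip table.

    Parameters
    ----------
    net : prior network providing the exon/transcript -> domain mappings.
    evidence : iterable of :class:`FeatureEvidence`.
    p_threshold : a domain is skipped when its Fisher-combined p-value is
        <= this threshold (ties count as skipped) and its mean effect is
        negative.
    strict_all_features : when True, additionally require every matched
        feature's individual p-value to pass the threshold.

    Domains with no matched feature are absent from the table (they are never
    skipped: absence of evidence is not evidence of skipping). Features that
    match no domain are logged and ignored.
    """
    feature_to_domains: dict[str, list] = {}
    for dom, feats in net.domain_to_exons.items():
        for f in feats:
            feature_to_domains.setdefault(f, []).append(dom)
    for dom, feats in net.domain_to_transcripts.items():
        for f in feats:
            feature_to_domains.setdefault(f, []).append(dom)

    per_domain: dict[tuple[str, str], list[FeatureEvidence]] = {}
    n_unmatched = 0
    for ev in evidence:
        doms = feature_to_domains.get(ev.feature_id)
        if not doms:
            n_unmatched += 1
            continue
        for dom in doms:
            per_domain.setdefault(dom, []).append(ev)
    if n_unmatched:
        logger.info("%d evidence features matched no domain", n_unmatched)
    if not per_domain:
        logger.warning("no evidence feature matched any domain; empty skip table")

    rows = []
    for dom in sorted(per_domain):
        evs = per_domain[dom]
        agg_p = fisher_aggregate([e.p_value for e in evs])
        eff = mean_effect([e.effect for e in evs])
        skipped = agg_p <= p_threshold and eff < 0
        if strict_all_features:
            skipped = skipped and all(e.p_value <= p_threshold for e in evs)
        rows.append(
            {
                "protein": dom[0],
                "domain": dom[1],
                "aggregated_p": agg_p,
                "mean_effect": eff,
                "n_features": len(evs),
                "skipped": skipped,
            }
        )
    return pd.DataFrame(rows, columns=SKIP_COLUMNS)


def skipped_domains(skip_table: pd.DataFrame) -> set[tuple[str, str]]:
    """The set of (protein, domain) pairs called skipped."""
    if skip_table.empty:
        return set()
    sub = skip_table[skip_table["skipped"]]
    return {(r.protein, r.domain) for r in sub.itertuples(index=False)}


def skip_scores(skip_table: pd.DataFrame, cap: float = 300.0) -> dict[tuple[str, str], float]:
    """-log10 aggregated p per skipped domain (capped), for soft-mode penalties."""
    scores: dict[tuple[str, str], float] = {}
    if skip_table.empty:
        return scores
    for r in skip_table[skip_table["skipped"]].itertuples(index=False):
        scores[(r.protein, r.domain)] = min(cap, -math.log10(max(r.aggregated_p, P_FLOOR)))
    return scores


def load_evidence(path) -> list[FeatureEvidence]:
    """Read evidence TSV with headers feature_id, feature_kind, effect, p_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "feature_kind", "effect", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"evidence file {path} missing columns {sorted(missing)}")
    return [
        FeatureEvidence(
            feature_id=str(r.feature_id),
            effect=float(r.effect),
            p_value=float(r.p_value),
            feature_kind=str(r.feature_kind),
        )
        for r in df.itertuples(index=False)
    ]


def write_evidence(evidence, path) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": e.feature_id,
                "feature_kind": e.feature_kind,
                "effect": e.effect,
                "p_value": e.p_value,
            }
            for e in evidence
        ]
    ).to_csv(path, sep="\t", index=False)


def write_skip_table(skip_table: pd.DataFrame, path) -> None:
    skip_table.to_csv(path, sep="\t", index=False)


def load_skip_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SKIP_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"skip table {path} missing columns {sorted(missing)}")
    return df[SKIP_COLUMNS]
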