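"""Seeded synthetic scenarios with planted ground truth.

The generator emulates the *input level* of the pipeline, not raw RNA-seq: a
layered, rooted domain-resolved interaction prior with a guaranteed
Perturbation-to-TF path per TF, regulons whose targets carry strongly
concordant differential statistics, and exon/transcript skip evidence planted
on chosen path domains so that a known set of interactions is abrogated in the
splice-aware analysis. Every quantity derives from one seeded generator, so a
scenario regenerates byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .prior import InteractionRecord, PriorNetwork, attach_perturbation, build_network, write_interaction_table
from .splice import FeatureEvidence, write_evidence
from .tf import Regulon
from .enrich import write_gmt


class GenerationError(ValueError):
    """The requested scenario parameters cannot be satisfied."""


@dataclass
class SyntheticScenario:
    records: list
    regulons: list
    gene_stats: dict
    evidence: list
    gene_sets: dict
    ground_truth: dict
    seed: int
    params: dict

    def network(self, directed_roots: bool = True) -> PriorNetwork:
        """Build the prior and attach the Perturbation root.

        On a direction-annotated prior the root is derived; otherwise the
        ground-truth root is passed explicitly.
        """
        net = build_network(self.records)
        if net.has_direction_annotation and directed_roots:
            return attach_perturbation(net)
        return attach_perturbation(net, roots=list(self.ground_truth["roots"]))


def generate_scenario(
    n_proteins: int = 8,
    n_domains_per_protein: int = 2,
    edge_density: float = 0.3,
    n_tfs: int = 1,
    n_skipped: int = 1,
    seed: int = 0,
    n_targets_per_tf: int = 15,
    n_background_genes: int = 150,
    include_null_evidence: bool = True,
    include_decoy_tf: bool = True,
    directed: bool = True,
) -> SyntheticScenario:
    """Generate a layered rooted scenario with planted skipped domains.

    One root protein feeds one or two intermediate layers that feed the TF
    layer; each TF has exactly one guaranteed path from the root, and no other
    edge enters a TF, so planting skip evidence on the TF-side domain of the
    final path edge abrogates the TF's only route. Extra edges are sampled
    between consecutive layers at ``edge_density`` (never into TFs).
    """
    if min(n_proteins, n_domains_per_protein, n_tfs) < 1 or n_skipped < 0:
        raise GenerationError("scenario parameters must be positive (n_skipped >= 0)")
    if not (0.0 <= edge_density <= 1.0):
        raise GenerationError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_decoy = 1 if include_decoy_tf and n_proteins >= n_tfs + 3 else 0
    n_mid = n_proteins - 1 - n_tfs - n_decoy
    if n_mid < 1:
        raise GenerationError(
            f"n_proteins={n_proteins} too small for 1 root + {n_tfs} TFs + an intermediate"
        )
    root = "PRX01"
    mids = [f"SIG{i + 1:02d}" for i in range(n_mid)]
    tfs = [f"TFA{i + 1:02d}" for i in range(n_tfs)]
    decoys = [f"TFB{i + 1:02d}" for i in range(n_decoy)]
    if n_mid >= 2:
        half = (n_mid + 1) // 2
        layers = [[root], mids[:half], mids[half:], tfs + decoys]
    else:
        layers = [[root], mids, tfs + decoys]

    domains = {p: [f"PF{pi:03d}{di:02d}" for di in range(n_domains_per_protein)]
               for pi, p in enumerate([root, *mids, *tfs, *decoys])}

    exon_counter = [0]
    tx_counter = [0]
    domain_exons: dict = {}
    domain_txs: dict = {}

    def features_of(protein: str, domain: str, n_exons: int):
        key = (protein, domain)
        if key not in domain_exons:
            ids = []
            for _ in range(n_exons):
                exon_counter[0] += 1
                ids.append(f"ENSE{exon_counter[0]:08d}")
            domain_exons[key] = ids
            if protein in tfs or protein in decoys:
                tx_counter[0] += 1
                domain_txs[key] = [f"ENST{tx_counter[0]:08d}"]
            else:
                domain_txs[key] = []
        return domain_exons[key], domain_txs[key]

    records: dict = {}

    def add_edge(src: str, src_dom: str, tgt: str, tgt_dom: str, n_exons: int = 1):
        rec = InteractionRecord(
            protein_a=src,
            domain_a=src_dom,
            protein_b=tgt,
            domain_b=tgt_dom,
            exons_a=tuple(features_of(src, src_dom, n_exons)[0]),
            exons_b=tuple(features_of(tgt, tgt_dom, n_exons)[0]),
            transcripts_a=tuple(features_of(src, src_dom, n_exons)[1]),
            transcripts_b=tuple(features_of(tgt, tgt_dom, n_exons)[1]),
            direction="ab" if directed else "",
        )
        # canonical() flips the direction tag when it swaps the endpoints,
        # so the upstream/downstream meaning survives canonicalization
        crec = rec.canonical()
        records[crec.key] = crec
        return crec.key

    # guaranteed root -> ... -> TF paths (domain 0 on each side, 2 exons)
    path_edges = []
    path_nodes_per_tf = {}
    mid_layers = layers[1:-1]
    for i, tf_name in enumerate(tfs):
        chain = [root]
        for layer in mid_layers:
            chain.append(layer[i % len(layer)])
        chain.append(tf_name)
        path_nodes_per_tf[tf_name] = chain
        for a, b in zip(chain[:-1], chain[1:]):
            key = add_edge(a, domains[a][0], b, domains[b][0], n_exons=2)
            path_edges.append(key)
    # decoy TFs hang off the last intermediate layer
    for j, d in enumerate(decoys):
        src = mid_layers[-1][j % len(mid_layers[-1])]
        add_edge(src, domains[src][0], d, domains[d][0])
    # extra edges between consecutive layers, never into real TFs
    for upper, lower in zip(layers[:-1], layers[1:]):
        for a in upper:
            for b in lower:
                if b in tfs or (a, b) in [(e[0][0], e[1][0]) for e in records]:
                    continue
                if rng.random() < edge_density:
                    da = domains[a][int(rng.integers(len(domains[a])))]
                    db = domains[b][int(rng.integers(len(domains[b])))]
                    add_edge(a, da, b, db)

    # choose planted skipped domains: TF-side domains of final path edges
    # first, then upstream path domains
    plant_slots = [(tf_name, domains[tf_name][0]) for tf_name in tfs]
    for tf_name in tfs:
        chain = path_nodes_per_tf[tf_name]
        plant_slots.extend((p, domains[p][0]) for p in chain[1:-1])
    # dedupe, preserve order
    seen = set()
    plant_slots = [s for s in plant_slots if not (s in seen or seen.add(s))]
    if n_skipped > len(plant_slots):
        raise GenerationError(
            f"n_skipped={n_skipped} exceeds available path-domain slots ({len(plant_slots)})"
        )
    planted = plant_slots[:n_skipped]

    evidence: list[FeatureEvidence] = []
    for dom in planted:
        for exon in domain_exons[dom]:
            evidence.append(
                FeatureEvidence(
                    feature_id=exon,
                    effect=float(-(0.3 + 0.3 * rng.random())),
                    p_value=float(10 ** -(2.5 + 1.5 * rng.random())),
                    feature_kind="exon",
                )
            )
        for tx in domain_txs[dom]:
            evidence.append(
                FeatureEvidence(
                    feature_id=tx,
                    effect=float(-(0.5 + rng.random())),
                    p_value=float(10 ** -(2.5 + 1.5 * rng.random())),
                    feature_kind="transcript",
                )
            )
    if include_null_evidence:
        planted_set = set(planted)
        candidates = sorted(d for d in domain_exons if d not in planted_set)
        n_null = min(3, len(candidates))
        for idx in rng.choice(len(candidates), size=n_null, replace=False) if n_null else []:
            dom = candidates[int(idx)]
            exon = domain_exons[dom][0]
            evidence.append(
                FeatureEvidence(
                    feature_id=exon,
                    effect=float(rng.uniform(-0.1, 0.15)),
                    p_value=float(rng.uniform(0.3, 0.9)),
                    feature_kind="exon",
                )
            )

    # regulons and expression statistics
    universe = [f"TG{i:04d}" for i in range(n_background_genes)]
    gene_stats = {g: float(rng.normal(0.0, 1.0)) for g in universe}
    shuffled = list(rng.permutation(universe))
    regulons = []
    offset = 0
    for tf_name in tfs + decoys:
        targets = shuffled[offset:offset + n_targets_per_tf]
        offset += n_targets_per_tf
        if len(targets) < n_targets_per_tf:
            raise GenerationError("n_background_genes too small for the requested regulons")
        modes = [1 if rng.random() < 0.8 else -1 for _ in targets]
        regulons.append(Regulon(tf=tf_name, targets=tuple(zip(targets, modes)), confidence="A"))
        if tf_name in tfs:  # concordant, strong signal
            for g, m in zip(targets, modes):
                gene_stats[g] = float(m * (3.5 + 0.5 * abs(rng.normal())))

    proteins_all = [root, *mids, *tfs, *decoys]
    true_path_proteins = sorted({p for c in path_nodes_per_tf.values() for p in c})
    rand1 = sorted(rng.choice(proteins_all, size=min(4, len(proteins_all)), replace=False))
    rand2 = sorted(rng.choice(proteins_all, size=min(4, len(proteins_all)), replace=False))
    gene_sets = {
        "PATHWAY_TRUE": set(true_path_proteins),
        "PATHWAY_RANDOM1": set(map(str, rand1)),
        "PATHWAY_RANDOM2": set(map(str, rand2)),
    }

    planted_set = set(planted)
    expected_abrogated = sorted(
        {key for key in records if key[0] in planted_set or key[1] in planted_set}
    )
    ground_truth = {
        "roots": [root],
        "tfs": tfs,
        "decoy_tfs": decoys,
        "path_edges": [_edge_to_list(k) for k in sorted(set(path_edges))],
        "planted_skipped_domains": [list(d) for d in planted],
        "expected_abrogated_edges": [_edge_to_list(k) for k in expected_abrogated],
    }
    params = {
        "n_proteins": n_proteins,
        "n_domains_per_protein": n_domains_per_protein,
        "edge_density": edge_density,
        "n_tfs": n_tfs,
        "n_skipped": n_skipped,
        "n_targets_per_tf": n_targets_per_tf,
        "n_background_genes": n_background_genes,
        "include_null_evidence": include_null_evidence,
        "include_decoy_tf": include_decoy_tf,
        "directed": directed,
    }
    return SyntheticScenario(
        records=[records[k] for k in sorted(records)],
        regulons=regulons,
        gene_stats=gene_stats,
        evidence=evidence,
        gene_sets=gene_sets,
        ground_truth=ground_truth,
        seed=seed,
        params=params,
    )


def _edge_to_list(key) -> list[str]:
    (pa, da), (pb, db) = key
    return [pa, da, pb, db]


def write_scenario(sc: SyntheticScenario, outdir) -> Path:
    """Write all standard pipeline inputs plus the ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_interaction_table(sc.records, outdir / "interactions.tsv")
    pd.DataFrame(
        [
            {"tf": r.tf, "target": g, "mode": m, "confidence": r.confidence or "A"}
            for r in sc.regulons
            for g, m in r.targets
        ]
    ).to_csv(outdir / "regulons.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "stat": sc.gene_stats[g]} for g in sorted(sc.gene_stats)]
    ).to_csv(outdir / "gene_stats.tsv", sep="\t", index=False)
    write_evidence(sc.evidence, outdir / "evidence.tsv")
    write_gmt(sc.gene_sets, outdir / "gene_sets.gmt")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sc.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config = {
        "interactions": "interactions.tsv",
        "regulons": "regulons.tsv",
        "gene_stats": "gene_stats.tsv",
        "evidence": "evidence.tsv",
        "gene_sets": "gene_sets.gmt",
        "roots": sc.ground_truth["roots"] if not sc.params["directed"] else None,
        "mode": "hard",
        "p_skip": 0.05,
        "p_tf": 0.05,
        "n_perm": 1000,
        "alpha": None,
        "lam": 0.01,
        "beta": None,
        "backend": "highs",
        "time_limit_s": 3600.0,
        "mip_gap": 0.0,
        "threads": 1,
        "seed": sc.seed,
        "k_max": 10,
        "tolerance": 0.0,
        "output_dir": "results",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return outdir


def random_tiny_instance(seed: int, max_proteins: int = 6, max_ddis: int = 8):
    """A random small prior + TF table + skip table for solver verification.

    Returns ``(net, tf_table, skip_table, params_dict)`` sized for the
    enumeration oracle: at most ``max_proteins`` proteins and ``max_ddis``
    DDIs, random TF weights/significance, optional skipped domains and random
    explicit roots.
    """
    from .ilp import IlpParams  # local import to avoid a cycle
    from .tf import TF_COLUMNS

    rng = np.random.default_rng(seed)
    n_prot = int(rng.integers(3, max_proteins + 1))
    proteins = [f"P{i + 1:02d}" for i in range(n_prot)]
    doms = {p: [f"D{i + 1}{j}" for j in range(int(rng.integers(1, 3)))]
            for i, p in enumerate(proteins)}
    all_domains = [(p, d) for p in proteins for d in doms[p]]

    n_ddis = int(rng.integers(2, max_ddis + 1))
    keys = set()
    attempts = 0
    while len(keys) < n_ddis and attempts < 200:
        attempts += 1
        a, b = all_domains[int(rng.integers(len(all_domains)))], all_domains[int(rng.integers(len(all_domains)))]
        if a == b:
            continue
        if a[0] == b[0] and rng.random() > 0.1:
            continue  # mostly avoid self-interactions
        keys.add((a, b) if a <= b else (b, a))
    records = []
    for (pa, da), (pb, db) in sorted(keys):
        direction = ""
        if rng.random() < 0.3:
            direction = "ab" if rng.random() < 0.5 else "ba"
        records.append(
            InteractionRecord(
                protein_a=pa, domain_a=da, protein_b=pb, domain_b=db,
                direction=direction,
            )
        )
    net = build_network(records)

    present = sorted(net.proteins)  # proteins actually touched by a DDI
    n_tfs = int(rng.integers(1, 3))
    tf_names = list(rng.choice(present, size=min(n_tfs, len(present)), replace=False))
    rows = []
    for t in tf_names:
        sig = bool(rng.random() < 0.8)
        weight = float(rng.uniform(0.3, 2.0))
        rows.append(
            {"tf": t, "score": weight, "empirical_p": 0.001 if sig else 0.5,
             "significant": sig, "weight": weight}
        )
    tf_table = pd.DataFrame(rows, columns=TF_COLUMNS)

    skip_rows = []
    if rng.random() < 0.6 and all_domains:
        n_skip = int(rng.integers(1, 3))
        for idx in rng.choice(len(all_domains), size=min(n_skip, len(all_domains)), replace=False):
            p, d = all_domains[int(idx)]
            skip_rows.append(
                {"protein": p, "domain": d,
                 "aggregated_p": float(10 ** -rng.uniform(1.5, 4.0)),
                 "mean_effect": float(-rng.uniform(0.2, 0.8)),
                 "n_features": 2, "skipped": True}
            )
    skip_table = pd.DataFrame(
        skip_rows,
        columns=["protein", "domain", "aggregated_p", "mean_effect", "n_features", "skipped"],
    )

    non_tf = [p for p in present if p not in tf_names] or present
    n_roots = int(rng.integers(1, min(3, len(non_tf)) + 1))
    roots = sorted(rng.choice(non_tf, size=n_roots, replace=False))
    attach_perturbation(net, roots=list(map(str, roots)))

    params = IlpParams(
        alpha=0.1,
        lam=float(rng.choice([0.005, 0.01, 0.05])),
        beta=float(rng.choice([0.01, 0.1])),
    )
    mode = "hard" if rng.random() < 0.5 else "soft"
    return net, tf_table, skip_table, params, mode
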