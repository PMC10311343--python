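"""Domain-resolved interaction prior.

The prior is a table of undirected domain-domain interactions (DDIs): each row
names two proteins (gene symbols), the Pfam domain on each side that mediates
the contact, and the Ensembl exon/transcript IDs that encode each domain.
Protein-protein interactions (PPIs) are the protein-level projection of the
DDIs; a PPI is functional only through at least one functional constituent DDI.

An auxiliary ``PERTURBATION`` root node represents the upstream cause of the
observed regulation; inferred paths originate there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

PERTURBATION = "PERTURBATION"

#: standard column names of the interaction table
STANDARD_COLUMNS = (
    "protein_a",
    "domain_a",
    "protein_b",
    "domain_b",
    "exons_a",
    "exons_b",
    "transcripts_a",
    "transcripts_b",
    "direction",
)
REQUIRED_COLUMNS = ("protein_a", "domain_a", "protein_b", "domain_b")


class ConfigurationError(ValueError):
    """A required column or setting could not be resolved."""


class InputError(ValueError):
    """Input data is empty or structurally invalid."""


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected DDI with its exon/transcript provenance.

    ``direction`` is an optional annotation: ``"ab"`` means protein_a is the
    upstream partner, ``"ba"`` the reverse, ``""`` unknown/undirected.
    """

    protein_a: str
    domain_a: str
    protein_b: str
    domain_b: str
    exons_a: tuple[str, ...] = ()
    exons_b: tuple[str, ...] = ()
    transcripts_a: tuple[str, ...] = ()
    transcripts_b: tuple[str, ...] = ()
    direction: str = ""

    def __post_init__(self) -> None:
        for name in ("protein_a", "domain_a", "protein_b", "domain_b"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value:
                raise InputError(f"{name} must be a non-empty string, got {value!r}")
        if self.direction not in ("", "ab", "ba"):
            raise InputError(f"direction must be '', 'ab' or 'ba', got {self.direction!r}")
        # feature lists are kept sorted and unique so records compare canonically
        for name in ("exons_a", "exons_b", "transcripts_a", "transcripts_b"):
            value = tuple(sorted(set(getattr(self, name))))
            object.__setattr__(self, name, value)

    @property
    def key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """Canonical undirected DDI key: endpoint (protein, domain) pairs, sorted."""
        a = (self.protein_a, self.domain_a)
        b = (self.protein_b, self.domain_b)
        return (a, b) if a <= b else (b, a)

    def canonical(self) -> "InteractionRecord":
        """Return the record with endpoints in canonical (sorted) order."""
        a = (self.protein_a, self.domain_a)
        b = (self.protein_b, self.domain_b)
        if a <= b:
            return self
        flipped = {"ab": "ba", "ba": "ab", "": ""}[self.direction]
        return InteractionRecord(
            protein_a=self.protein_b,
            domain_a=self.domain_b,
            protein_b=self.protein_a,
            domain_b=self.domain_a,
            exons_a=self.exons_b,
            exons_b=self.exons_a,
            transcripts_a=self.transcripts_b,
            transcripts_b=self.transcripts_a,
            direction=flipped,
        )

    @property
    def is_self_interaction(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass
class PriorNetwork:
    """Domain-resolved interaction graph plus the Perturbation root.

    Attributes
    ----------
    proteins : set of gene symbols.
    domains : set of (protein, Pfam) pairs.
    ddis : dict mapping each canonical DDI key to its annotation dict with keys
        ``direction`` ('' / 'ab' / 'ba', in canonical endpoint order) and
        ``self_interaction``.
    ppis : dict mapping canonical (protein_a, protein_b) pairs to the list of
        constituent DDI keys.
    domain_to_exons, domain_to_transcripts : feature mappings per domain.
    perturbation_targets : proteins linked from the PERTURBATION root
        (empty until :func:`attach_perturbation` is called).
    """

    proteins: set[str] = field(default_factory=set)
    domains: set[tuple[str, str]] = field(default_factory=set)
    ddis: dict = field(default_factory=dict)
    ppis: dict = field(default_factory=dict)
    domain_to_exons: dict = field(default_factory=dict)
    domain_to_transcripts: dict = field(default_factory=dict)
    perturbation_targets: set[str] = field(default_factory=set)

    @property
    def has_direction_annotation(self) -> bool:
        return any(info["direction"] for info in self.ddis.values())

    def ppi_key_of(self, ddi_key) -> tuple[str, str]:
        (pa, _), (pb, _) = ddi_key
        return (pa, pb) if pa <= pb else (pb, pa)

    def ddi_direction(self, ddi_key) -> str:
        return self.ddis[ddi_key]["direction"]

    def allowed_orientations(self, ddi_key) -> tuple[str, ...]:
        """Directed orientations a DDI may take: 'ab' = first canonical
        endpoint upstream. Self-interactions mediate no direction."""
        info = self.ddis[ddi_key]
        if info["self_interaction"]:
            return ()
        if info["direction"]:
            return (info["direction"],)
        return ("ab", "ba")

    def validate(self) -> None:
        """Raise :class:`InputError` on a structural inconsistency."""
        for (a, b) in self.ddis:
            for endpoint in (a, b):
                if endpoint not in self.domains:
                    raise InputError(f"DDI endpoint {endpoint} is not a registered domain")
        for pair, ddi_keys in self.ppis.items():
            if not ddi_keys:
                raise InputError(f"PPI {pair} has no constituent DDI")
        for protein, _ in self.domains:
            if protein not in self.proteins:
                raise InputError(f"domain carrier {protein} missing from proteins")
        if PERTURBATION in self.proteins:
            raise InputError("PERTURBATION must not be a real protein")


def _split_list(cell: str, sep: str) -> tuple[str, ...]:
    if not cell or cell.lower() in ("nan", "na"):
        return ()
    return tuple(sorted({tok.strip() for tok in cell.split(sep) if tok.strip()}))


def load_interaction_table(
    path,
    dialect: dict[str, str] | None = None,
    list_sep: str = ";",
) -> list[InteractionRecord]:
    """Read a delimited DDI table and return validated, de-duplicated records.

    Parameters
    ----------
    path : path to a tab-separated file with the standard headers
        (``protein_a domain_a protein_b domain_b exons_a exons_b transcripts_a
        transcripts_b [direction]``).
    dialect : optional mapping from standard column names to the names used in
        the file, for exports with different headers.
    list_sep : separator inside exon/transcript list cells (default ``;``).

    Duplicate DDIs (same canonical endpoint pairs) are collapsed with merged
    exon/transcript lists; rows failing validation are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] == 0 or (df.shape[0] == 0 and df.shape[1] == 0):
        raise InputError(f"interaction table {path} is empty")
    dialect = dialect or {}
    colmap = {std: dialect.get(std, std) for std in STANDARD_COLUMNS}
    for std in REQUIRED_COLUMNS:
        if colmap[std] not in df.columns:
            raise ConfigurationError(
                f"required column {colmap[std]!r} (for {std!r}) not found in {path}"
            )
    if df.shape[0] == 0:
        raise InputError(f"interaction table {path} has no data rows")

    records: dict = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()

        def get(std: str) -> str:
            col = colmap[std]
            return str(row[col]).strip() if col in row else ""

        try:
            rec = InteractionRecord(
                protein_a=get("protein_a"),
                domain_a=get("domain_a"),
                protein_b=get("protein_b"),
                domain_b=get("domain_b"),
                exons_a=_split_list(get("exons_a"), list_sep),
                exons_b=_split_list(get("exons_b"), list_sep),
                transcripts_a=_split_list(get("transcripts_a"), list_sep),
                transcripts_b=_split_list(get("transcripts_b"), list_sep),
                direction=get("direction"),
            ).canonical()
        except InputError as exc:
            n_dropped += 1
            logger.warning("dropping malformed interaction row: %s", exc)
            continue
        key = rec.key
        if key in records:
            records[key] = _merge(records[key], rec)
        else:
            records[key] = rec
    if n_dropped:
        logger.warning("dropped %d malformed rows from %s", n_dropped, path)
    if not records:
        raise InputError(f"no valid interaction rows in {path}")
    return [records[k] for k in sorted(records)]


def _merge(a: InteractionRecord, b: InteractionRecord) -> InteractionRecord:
    """Merge two rows describing the same canonical DDI (e.g. isoform rows)."""
    direction = a.direction if a.direction == b.direction else ""
    return replace(
        a,
        exons_a=tuple(sorted(set(a.exons_a) | set(b.exons_a))),
        exons_b=tuple(sorted(set(a.exons_b) | set(b.exons_b))),
        transcripts_a=tuple(sorted(set(a.transcripts_a) | set(b.transcripts_a))),
        transcripts_b=tuple(sorted(set(a.transcripts_b) | set(b.transcripts_b))),
        direction=direction,
    )


def write_interaction_table(records, path, list_sep: str = ";") -> None:
    """Write records back to the standard TSV layout (canonical ordering)."""
    rows = []
    for rec in sorted((r.canonical() for r in records), key=lambda r: r.key):
        rows.append(
            {
                "protein_a": rec.protein_a,
                "domain_a": rec.domain_a,
                "protein_b": rec.protein_b,
                "domain_b": rec.domain_b,
                "exons_a": list_sep.join(rec.exons_a),
                "exons_b": list_sep.join(rec.exons_b),
                "transcripts_a": list_sep.join(rec.transcripts_a),
                "transcripts_b": list_sep.join(rec.transcripts_b),
                "direction": rec.direction,
            }
        )
    pd.DataFrame(rows, columns=list(STANDARD_COLUMNS)).to_csv(path, sep="\t", index=False)


def build_network(records) -> PriorNetwork:
    """Assemble a :class:`PriorNetwork` from interaction records.

    PPIs are the protein-pair projection of the DDIs; each PPI stores all its
    constituent DDI keys. Self-interactions (both domains on one protein) are
    retained but flagged and never used for reachability.
    """
    records = [r.canonical() for r in records]
    if not records:
        raise InputError("cannot build a network from zero records")
    net = PriorNetwork()
    for rec in records:
        key = rec.key
        (pa, da), (pb, db) = key
        net.proteins.update((pa, pb))
        net.domains.update(((pa, da), (pb, db)))
        # exon/transcript lists follow the canonical endpoint order
        crec = rec  # already canonical
        for dom, exons, txs in (
            ((crec.protein_a, crec.domain_a), crec.exons_a, crec.transcripts_a),
            ((crec.protein_b, crec.domain_b), crec.exons_b, crec.transcripts_b),
        ):
            if exons:
                merged = set(net.domain_to_exons.get(dom, ())) | set(exons)
                net.domain_to_exons[dom] = tuple(sorted(merged))
            if txs:
                merged = set(net.domain_to_transcripts.get(dom, ())) | set(txs)
                net.domain_to_transcripts[dom] = tuple(sorted(merged))
        if key in net.ddis:
            if net.ddis[key]["direction"] != crec.direction:
                net.ddis[key]["direction"] = ""
            continue
        net.ddis[key] = {
            "direction": crec.direction,
            "self_interaction": rec.is_self_interaction,
        }
        ppi = (pa, pb) if pa <= pb else (pb, pa)
        net.ppis.setdefault(ppi, []).append(key)
    net.validate()
    return net


def attach_perturbation(
    net: PriorNetwork,
    roots: list[str] | None = None,
    tfs: set[str] | frozenset[str] = frozenset(),
) -> PriorNetwork:
    """Designate the proteins reachable directly from the PERTURBATION root.

    When ``roots`` is given, it is validated against the network. Otherwise,
    if the prior carries direction annotations, roots are the proteins with no
    annotated incoming edge ("no upstream regulator"). On a fully undirected
    prior every protein except the supplied ``tfs`` is a candidate root and
    the inference's size regularization selects among them.

    Perturbation links are directed and protein-level only: the root carries
    no domain and participates in no DDI.
    """
    if roots is not None:
        missing = [r for r in roots if r not in net.proteins]
        if missing:
            raise InputError(f"explicit roots not in network: {missing}")
        net.perturbation_targets = set(roots)
        return net
    if net.has_direction_annotation:
        has_incoming: set[str] = set()
        for key, info in net.ddis.items():
            (pa, _), (pb, _) = key
            if info["direction"] == "ab":
                has_incoming.add(pb)
            elif info["direction"] == "ba":
                has_incoming.add(pa)
        net.perturbation_targets = set(net.proteins) - has_incoming
    else:
        net.perturbation_targets = set(net.proteins) - set(tfs)
    return net


def export_sif(net: PriorNetwork, edge_path, node_path) -> None:
    """SIF-like TSV export: (source, interaction_type, target) plus node attributes."""
    edges = []
    for key in sorted(net.ddis):
        (pa, da), (pb, db) = key
        edges.append((f"{pa}:{da}", "ddi", f"{pb}:{db}"))
    for pair in sorted(net.ppis):
        edges.append((pair[0], "ppi", pair[1]))
    for target in sorted(net.perturbation_targets):
        edges.append((PERTURBATION, "perturbation", target))
    pd.DataFrame(edges, columns=["source", "interaction_type", "target"]).to_csv(
        edge_path, sep="\t", index=False
    )
    nodes = [{"node": PERTURBATION, "kind": "perturbation", "protein": ""}]
    for p in sorted(net.proteins):
        nodes.append({"node": p, "kind": "protein", "protein": p})
    for p, d in sorted(net.domains):
        nodes.append({"node": f"{p}:{d}", "kind": "domain", "protein": p})
    pd.DataFrame(nodes).to_csv(node_path, sep="\t", index=False)
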