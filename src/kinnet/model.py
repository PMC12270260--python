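"""Core data model: phosphosites, kinases, and the directed bipartite
kinase interaction network (KIN), plus tabular readers/writers.

A KIN has two node classes — kinases and phosphorylation sites — and two
directed edge classes: kinase→site edges (``e_ks``, "k phosphorylates s")
and site→kinase edges (``e_sk``, "s is a phosphosite located on kinase k").
The baseline network, every intermediate filtered network, and the final
differential network are all instances of this one type.

Positions are 1-based protein residue numbering throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 standard amino-acid one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: padding character used where a flank runs past the protein terminus
PAD = "_"

_SITE_ID_RE = re.compile(r"^(?P<protein>[^_]+)_(?P<residue>[STY]?)(?P<position>\d+)$")


class KinaseType(str, Enum):
    """Kinase specificity class: serine/threonine or tyrosine kinases."""

    SER_THR = "SER_THR"
    TYR = "TYR"

    @staticmethod
    def for_residue(residue: str) -> "KinaseType":
        if residue in ("S", "T"):
            return KinaseType.SER_THR
        if residue == "Y":
            return KinaseType.TYR
        raise ValueError(f"no kinase type for residue {residue!r}")


class ParseError(ValueError):
    """Raised when a tabular input cannot be parsed."""


@dataclass(frozen=True)
class Site:
    """A phosphorylation site: one S/T/Y residue on one protein.

    Parameters
    ----------
    protein : str
        UniProt accession of the host protein.
    position : int
        1-based residue index within the protein sequence.
    residue : str
        One of ``S``, ``T``, ``Y``.
    flank : str
        Amino acids centered on the site; padded with ``_`` where the
        protein sequence ends. May be empty when unknown.
    """

    protein: str
    position: int
    residue: str
    flank: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if self.residue not in "STY":
            raise ValueError(f"residue must be S, T or Y, got {self.residue!r}")
        if self.flank:
            center = self.flank[len(self.flank) // 2]
            if center != PAD and center != self.residue:
                raise ValueError(
                    f"flank center {center!r} does not match residue {self.residue!r}"
                )

    @property
    def id(self) -> str:
        """Canonical identifier, e.g. ``P19338_S67``."""
        return f"{self.protein}_{self.residue}{self.position}"

    @property
    def ktype(self) -> KinaseType:
        """The kinase class able to phosphorylate this residue."""
        return KinaseType.for_residue(self.residue)


def parse_site_id(site_id: str, flank: str = "") -> Site:
    """Parse a canonical site id into a :class:`Site`.

    Accepts ``ACCESSION_<residue><position>`` (e.g. ``Q9UNZ2_S176``) and
    ``ACCESSION_<position>``; in the latter form the residue is taken from
    the center of *flank*.
    """
    m = _SITE_ID_RE.match(site_id)
    if m is None:
        raise ParseError(f"malformed site id {site_id!r}")
    residue = m.group("residue")
    if not residue:
        if not flank:
            raise ParseError(
                f"site id {site_id!r} lacks a residue letter and no flank was given"
            )
        residue = flank[len(flank) // 2]
    if residue not in "STY":
        raise ParseError(f"site id {site_id!r}: residue {residue!r} not in S/T/Y")
    return Site(
        protein=m.group("protein"),
        position=int(m.group("position")),
        residue=residue,
        flank=flank,
    )


@dataclass(frozen=True)
class Kinase:
    """A kinase node.

    ``site_ids`` lists the measured phosphosites located *on* this kinase
    (the sources of its incoming site→kinase edges); it may be empty.
    """

    id: str
    ktype: KinaseType
    site_ids: frozenset[str] = frozenset()

    def targets_residue(self, residue: str) -> bool:
        return KinaseType.for_residue(residue) is self.ktype


@dataclass(frozen=True)
class ReferenceEdgeSet:
    """Curated kinase→site interactions used as the evaluation reference."""

    edges: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.edges)


class KINError(ValueError):
    """Raised when a KIN invariant would be violated."""


class KIN:
    """Directed bipartite kinase interaction network.

    Nodes are kinases and sites; edges are kinase→site (``e_ks``) and
    site→kinase (``e_sk``) pairs. Edge attributes (PSSM score, background
    percentile, log2 fold change) live in ``edge_attrs`` keyed by the
    directed pair.
    """

    def __init__(self) -> None:
        self.kinases: dict[str, Kinase] = {}
        self.sites: dict[str, Site] = {}
        self.e_ks: set[tuple[str, str]] = set()
        self.e_sk: set[tuple[str, str]] = set()
        self.edge_attrs: dict[tuple[str, str], dict] = {}
        # kinase id -> UniProt accession of the kinase protein (identity
        # unless a mapping table was supplied)
        self.accession_of: dict[str, str] = {}

    # -- construction ------------------------------------------------------

    def add_kinase(self, kinase: Kinase, accession: str | None = None) -> None:
        self.kinases[kinase.id] = kinase
        self.accession_of[kinase.id] = accession if accession is not None else kinase.id

    def add_site(self, site: Site) -> None:
        self.sites[site.id] = site

    def add_edge_ks(self, kinase_id: str, site_id: str, **attrs) -> None:
        if kinase_id not in self.kinases:
            raise KINError(f"KS edge from unknown kinase {kinase_id!r}")
        if site_id not in self.sites:
            raise KINError(f"KS edge to unknown site {site_id!r}")
        site = self.sites[site_id]
        if not self.kinases[kinase_id].targets_residue(site.residue):
            raise KINError(
                f"incompatible KS edge: {self.kinases[kinase_id].ktype.value} "
                f"kinase {kinase_id!r} -> {site.residue} site {site_id!r}"
            )
        self.e_ks.add((kinase_id, site_id))
        if attrs:
            self.edge_attrs.setdefault((kinase_id, site_id), {}).update(attrs)

    def add_edge_sk(self, site_id: str, kinase_id: str, **attrs) -> None:
        if kinase_id not in self.kinases:
            raise KINError(f"SK edge to unknown kinase {kinase_id!r}")
        if site_id not in self.sites:
            raise KINError(f"SK edge from unknown site {site_id!r}")
        self.e_sk.add((site_id, kinase_id))
        k = self.kinases[kinase_id]
        if site_id not in k.site_ids:
            self.kinases[kinase_id] = replace(k, site_ids=k.site_ids | {site_id})
        if attrs:
            self.edge_attrs.setdefault((site_id, kinase_id), {}).update(attrs)

    # -- inspection --------------------------------------------------------

    @property
    def node_ids(self) -> set[str]:
        return set(self.kinases) | set(self.sites)

    def n_edges(self) -> int:
        return len(self.e_ks) + len(self.e_sk)

    def degree(self, node_id: str) -> int:
        """Total degree over both edge classes."""
        d = 0
        for k, s in self.e_ks:
            if node_id in (k, s):
                d += 1
        for s, k in self.e_sk:
            if node_id in (k, s):
                d += 1
        return d

    def out_sites(self, kinase_id: str) -> set[str]:
        """Out-neighborhood N+(k): the sites this kinase targets."""
        return {s for k, s in self.e_ks if k == kinase_id}

    def host_kinase(self, site_id: str) -> str | None:
        """The kinase this site is located on, if it is in the network.

        Resolution order: explicit registration via a site→kinase edge,
        then accession equality between the site's protein and a kinase.
        """
        for kid, kin in self.kinases.items():
            if site_id in kin.site_ids:
                return kid
        site = self.sites.get(site_id)
        if site is None:
            return None
        for kid, acc in self.accession_of.items():
            if acc == site.protein and kid in self.kinases:
                return kid
        return None

    def validate(self) -> None:
        """Raise :class:`KINError` on the first invariant violation."""
        for k, s in self.e_ks:
            if k not in self.kinases or s not in self.sites:
                raise KINError(f"KS edge ({k}, {s}) has a missing endpoint")
            if not self.kinases[k].targets_residue(self.sites[s].residue):
                raise KINError(f"KS edge ({k}, {s}) violates residue compatibility")
        for s, k in self.e_sk:
            if k not in self.kinases or s not in self.sites:
                raise KINError(f"SK edge ({s}, {k}) has a missing endpoint")
            if s not in self.kinases[k].site_ids:
                raise KINError(f"SK edge ({s}, {k}): site not registered on kinase")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KIN):
            return NotImplemented
        return (
            set(self.kinases) == set(other.kinases)
            and set(self.sites) == set(other.sites)
            and self.e_ks == other.e_ks
            and self.e_sk == other.e_sk
        )

    # -- transformation ----------------------------------------------------

    def copy(self) -> "KIN":
        out = KIN()
        out.kinases = dict(self.kinases)
        out.sites = dict(self.sites)
        out.e_ks = set(self.e_ks)
        out.e_sk = set(self.e_sk)
        out.edge_attrs = {e: dict(a) for e, a in self.edge_attrs.items()}
        out.accession_of = dict(self.accession_of)
        return out

    def restrict(
        self,
        kinase_ids: set[str] | None = None,
        site_ids: set[str] | None = None,
        edges: set[tuple[str, str]] | None = None,
    ) -> "KIN":
        """Subgraph with the given nodes (None = keep all) and, optionally,
        only the given directed edges. Dangling edges are dropped; site
        registrations on kinases are restricted accordingly.
        """
        keep_k = set(self.kinases) if kinase_ids is None else kinase_ids & set(self.kinases)
        keep_s = set(self.sites) if site_ids is None else site_ids & set(self.sites)
        out = KIN()
        for kid in keep_k:
            k = self.kinases[kid]
            out.kinases[kid] = replace(k, site_ids=frozenset(k.site_ids & keep_s))
            out.accession_of[kid] = self.accession_of.get(kid, kid)
        out.sites = {sid: self.sites[sid] for sid in keep_s}
        for k, s in self.e_ks:
            if k in keep_k and s in keep_s and (edges is None or (k, s) in edges):
                out.e_ks.add((k, s))
        for s, k in self.e_sk:
            if s in keep_s and k in keep_k and (edges is None or (s, k) in edges):
                out.e_sk.add((s, k))
        out.edge_attrs = {
            e: dict(a)
            for e, a in self.edge_attrs.items()
            if e in out.e_ks or e in out.e_sk
        }
        # drop registrations for sites whose SK edge disappeared but keep
        # ones implied by surviving SK edges
        hosted: dict[str, set[str]] = {kid: set() for kid in out.kinases}
        for s, k in out.e_sk:
            hosted[k].add(s)
        for kid, k in list(out.kinases.items()):
            out.kinases[kid] = replace(k, site_ids=frozenset(hosted[kid]))
        return out

    def induced_on_sites(self, site_ids: set[str]) -> "KIN":
        """Induced subgraph G[K ∪ S'] followed by singleton pruning: the
        contract shared by both node filters (no kinase is removed except
        by pruning)."""
        return prune_singletons(self.restrict(site_ids=site_ids))


def prune_singletons(kin: KIN) -> KIN:
    """Remove all nodes with total degree zero. Idempotent; edges untouched.

    Isolated nodes carry no information in an interaction network, so every
    filter applies this implicitly.
    """
    touched: set[str] = set()
    for k, s in kin.e_ks:
        touched.add(k)
        touched.add(s)
    for s, k in kin.e_sk:
        touched.add(k)
        touched.add(s)
    return kin.restrict(
        kinase_ids=set(kin.kinases) & touched, site_ids=set(kin.sites) & touched
    )


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def read_site_table(path: str | Path) -> list[Site]:
    """Read a site table (TSV with columns ``id`` and ``flank``, or
    ``protein``/``position``/``residue`` and ``flank``).

    Duplicate ids collapse to the first occurrence with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    sites: list[Site] = []
    seen: set[str] = set()
    dups = 0
    for i, row in df.iterrows():
        try:
            flank = row.get("flank", "") or ""
            if "id" in df.columns and row["id"]:
                site = parse_site_id(row["id"], flank=flank)
            else:
                site = Site(
                    protein=row["protein"],
                    position=int(row["position"]),
                    residue=row["residue"],
                    flank=flank,
                )
        except (ParseError, ValueError, KeyError) as exc:
            raise ParseError(f"{path}, row {i + 2}: {exc}") from exc
        if site.id in seen:
            dups += 1
            continue
        seen.add(site.id)
        sites.append(site)
    if dups:
        logger.warning("%s: collapsed %d duplicate site rows (first wins)", path, dups)
    return sites


def write_site_table(sites: list[Site], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in sites],
            "flank": [s.flank for s in sites],
            "protein": [s.protein for s in sites],
            "position": [s.position for s in sites],
            "residue": [s.residue for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)


_EDGE_COLS = ["source", "target", "edge_type", "kinase_type", "score", "percentile", "log2fc"]


def write_kin(kin: KIN, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize a KIN as an edge-list TSV or GraphML.

    The TSV has one row per directed edge with columns source, target,
    edge_type (KS/SK), kinase_type, and the numeric attributes score,
    percentile and log2fc.
    """
    kin.validate()
    if fmt == "graphml":
        nx.write_graphml(to_networkx(kin), str(path))
        return
    rows = []
    for k, s in sorted(kin.e_ks):
        a = kin.edge_attrs.get((k, s), {})
        rows.append(
            {
                "source": k,
                "target": s,
                "edge_type": "KS",
                "kinase_type": kin.kinases[k].ktype.value,
                "score": a.get("score", ""),
                "percentile": a.get("percentile", ""),
                "log2fc": a.get("log2fc", ""),
            }
        )
    for s, k in sorted(kin.e_sk):
        a = kin.edge_attrs.get((s, k), {})
        rows.append(
            {
                "source": s,
                "target": k,
                "edge_type": "SK",
                "kinase_type": kin.kinases[k].ktype.value,
                "score": a.get("score", ""),
                "percentile": a.get("percentile", ""),
                "log2fc": a.get("log2fc", ""),
            }
        )
    pd.DataFrame(rows, columns=_EDGE_COLS).to_csv(path, sep="\t", index=False)


def read_kin(path: str | Path, fmt: str = "tsv") -> KIN:
    """Read a KIN written by :func:`write_kin`; inverse on node sets, edge
    sets and numeric attributes."""
    if fmt == "graphml":
        return from_networkx(nx.read_graphml(str(path)))
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    kin = KIN()
    pending_sk: list[tuple[str, str, dict]] = []
    for i, row in df.iterrows():
        etype = row["edge_type"]
        if etype not in ("KS", "SK"):
            raise ParseError(f"{path}, row {i + 2}: unknown edge_type {etype!r}")
        kid, sid = (row["source"], row["target"]) if etype == "KS" else (row["target"], row["source"])
        site = parse_site_id(sid)
        declared = row.get("kinase_type", "")
        ktype = KinaseType(declared) if declared else KinaseType.for_residue(site.residue)
        if kid in kin.kinases and kin.kinases[kid].ktype is not ktype:
            raise ParseError(
                f"{path}, row {i + 2}: kinase {kid!r} declared as both "
                f"{kin.kinases[kid].ktype.value} and {ktype.value}"
            )
        if kid not in kin.kinases:
            kin.add_kinase(Kinase(id=kid, ktype=ktype))
        if sid not in kin.sites:
            kin.add_site(site)
        attrs = {
            key: float(row[key])
            for key in ("score", "percentile", "log2fc")
            if key in df.columns and row[key] != ""
        }
        if etype == "KS":
            try:
                kin.add_edge_ks(kid, sid, **attrs)
            except KINError as exc:
                raise ParseError(f"{path}, row {i + 2}: {exc}") from exc
        else:
            pending_sk.append((sid, kid, attrs))
    for sid, kid, attrs in pending_sk:
        kin.add_edge_sk(sid, kid, **attrs)
    return kin


def to_networkx(kin: KIN) -> nx.DiGraph:
    """Convert to a networkx DiGraph with typed node/edge attributes."""
    g = nx.DiGraph()
    for kid, k in kin.kinases.items():
        g.add_node(kid, kind="kinase", ktype=k.ktype.value,
                   accession=kin.accession_of.get(kid, kid))
    for sid, s in kin.sites.items():
        g.add_node(sid, kind="site", protein=s.protein, position=s.position,
                   residue=s.residue, flank=s.flank)
    for k, s in kin.e_ks:
        g.add_edge(k, s, edge_type="KS", **kin.edge_attrs.get((k, s), {}))
    for s, k in kin.e_sk:
        g.add_edge(s, k, edge_type="SK", **kin.edge_attrs.get((s, k), {}))
    return g


def from_networkx(g: nx.DiGraph) -> KIN:
    kin = KIN()
    for node, d in g.nodes(data=True):
        if d.get("kind") == "kinase":
            kin.add_kinase(
                Kinase(id=node, ktype=KinaseType(d["ktype"])),
                accession=d.get("accession", node),
            )
        else:
            kin.add_site(
                Site(
                    protein=d["protein"],
                    position=int(d["position"]),
                    residue=d["residue"],
                    flank=d.get("flank", ""),
                )
            )
    for u, v, d in g.edges(data=True):
        attrs = {k: v2 for k, v2 in d.items() if k != "edge_type"}
        if d.get("edge_type") == "KS":
            kin.add_edge_ks(u, v, **attrs)
        else:
            kin.add_edge_sk(u, v, **attrs)
    return kin


def read_reference_edges(path: str | Path) -> ReferenceEdgeSet:
    """Read a reference edge table: TSV with columns ``kinase`` and ``site``
    (canonical site ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ReferenceEdgeSet(
        edges=frozenset(zip(df["kinase"].tolist(), df["site"].tolist()))
    )


def write_reference_edges(ref: ReferenceEdgeSet, path: str | Path) -> None:
    pd.DataFrame(sorted(ref.edges), columns=["kinase", "site"]).to_csv(
        path, sep="\t", index=False
    )


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column kinase→accession mapping table (TSV, no header required
    if columns are named ``kinase_id`` and ``accession``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if "kinase_id" in cols and "accession" in cols:
        return dict(zip(df["kinase_id"], df["accession"]))
    return dict(zip(df[cols[0]], df[cols[1]]))
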