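"""Node and edge filters that carve a differential subnetwork out of the
baseline KIN.

Node filters (applied to substrate nodes only; kinases leave only by
singleton pruning):

* FS — keep sites whose precomputed functional score g(s) >= beta
  (default 0.4); removes sites unlikely to matter for the protein.
* DIFF — keep sites with |log2 fold change| >= gamma (default 1).

Edge filters:

* CORR — for kinase→site edges whose target site lies on another kinase
  k(s), demand that phosphorylation of s co-varies with at least one of
  k(s)'s own targets (|Pearson r| >= delta, adjusted P < epsilon).
  Edges onto non-kinase proteins are never touched.
* PCST — cast subnetwork extraction as a prize-collecting Steiner tree on
  the undirected projection: substrate prizes |f_s|, kinase prizes gamma,
  unit edge weights; the solution tree, directions restored, is the
  filtered network.

Every filter returns a subgraph of its input, is idempotent, and ends
with singleton pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import KIN, prune_singletons
from .pcst import PCSTInstance, solve_pcst

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# node filters
# ---------------------------------------------------------------------------

def filter_fs(
    kin: KIN,
    g: Mapping[str, float] | pd.Series,
    beta: float = 0.4,
    keep_unscored: bool = False,
) -> KIN:
    """Functional-score node filter: keep sites with g(s) >= beta.

    Sites absent from *g* are removed by default (they cannot demonstrate
    functional relevance); set ``keep_unscored`` to retain them.
    """
    if isinstance(g, pd.Series):
        g = g.to_dict()
    for sid, val in g.items():
        if not 0.0 <= float(val) <= 1.0:
            raise ValueError(f"functional score for {sid} outside [0, 1]: {val}")
    unscored = [sid for sid in kin.sites if sid not in g]
    if unscored and not keep_unscored:
        logger.info("FS: %d unscored sites removed", len(unscored))
    keep = {
        sid
        for sid in kin.sites
        if (sid in g and float(g[sid]) >= beta) or (sid not in g and keep_unscored)
    }
    return kin.induced_on_sites(keep)


def filter_diff(
    kin: KIN, f: Mapping[str, float] | pd.Series, gamma: float = 1.0
) -> KIN:
    """Differential-phosphorylation node filter: keep sites with
    |f_s| >= gamma. Sites with no fold change are removed."""
    if isinstance(f, pd.Series):
        f = f.to_dict()
    keep = {sid for sid in kin.sites if sid in f and abs(float(f[sid])) >= gamma}
    return kin.induced_on_sites(keep)


# ---------------------------------------------------------------------------
# CORR edge filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrResult:
    """One tested co-phosphorylation pair."""

    site: str
    other: str
    r: float
    p_raw: float
    p_adj: float


_CORRECTIONS = {"BH": "fdr_bh", "bonferroni": "bonferroni", "none": None}


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float] | None:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return None
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None  # constant column: correlation undefined
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def corr_test(
    kin: KIN,
    x: pd.DataFrame,
    correction: str = "BH",
    exclude_self: bool = False,
) -> tuple[list[CorrResult], dict[tuple[str, str], list[CorrResult]]]:
    """Run all co-phosphorylation tests for one intensity matrix.

    Returns the flat list of tested pairs (one multiple-testing family per
    invocation) and a map from each eligible kinase→site edge to its
    tests.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; use BH, bonferroni or none")
    eligible: dict[tuple[str, str], str] = {}  # edge -> host kinase k(s)
    for k, s in sorted(kin.e_ks):
        host = kin.host_kinase(s)
        if host is None:
            continue
        if exclude_self and host == k:
            continue
        eligible[(k, s)] = host

    tests: list[CorrResult] = []
    seen_pairs: dict[tuple[str, str], int] = {}
    edge_tests: dict[tuple[str, str], list[int]] = {e: [] for e in eligible}
    skipped = 0
    for edge, host in eligible.items():
        _, s = edge
        for s2 in sorted(kin.out_sites(host)):
            pair = (s, s2)
            if pair not in seen_pairs:
                if s not in x.columns or s2 not in x.columns:
                    skipped += 1
                    seen_pairs[pair] = -1
                else:
                    res = _pearson(x[s].to_numpy(float), x[s2].to_numpy(float))
                    if res is None:
                        skipped += 1
                        seen_pairs[pair] = -1
                    else:
                        seen_pairs[pair] = len(tests)
                        tests.append(CorrResult(s, s2, res[0], res[1], np.nan))
            if seen_pairs[pair] >= 0:
                edge_tests[edge].append(seen_pairs[pair])
    if skipped:
        logger.info("CORR: %d site pairs skipped (missing data, <3 complete "
                    "observations, or zero variance)", skipped)

    method = _CORRECTIONS[correction]
    if tests:
        raw = np.array([t.p_raw for t in tests])
        adj = raw if method is None else multipletests(raw, method=method)[1]
        tests = [
            CorrResult(t.site, t.other, t.r, t.p_raw, float(a))
            for t, a in zip(tests, adj)
        ]
    return tests, {e: [tests[i] for i in idxs] for e, idxs in edge_tests.items()}


def filter_corr(
    kin: KIN,
    x: pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame],
    delta: float = 0.8,
    epsilon: float = 0.05,
    correction: str = "BH",
    exclude_self: bool = False,
) -> KIN | tuple[KIN, KIN]:
    """Co-phosphorylation edge filter.

    Only kinase→site edges whose target site sits on a kinase present in
    the network are eligible; such an edge survives iff some target s' of
    the host kinase shows |r(X_s, X_s')| >= delta with adjusted P <
    epsilon. All other edges (kinase→non-kinase protein, site→kinase) are
    kept. With two condition matrices the filter runs per condition and
    returns one network per condition.
    """
    if isinstance(x, tuple):
        return tuple(
            filter_corr(kin, xi, delta, epsilon, correction, exclude_self) for xi in x
        )
    _, edge_tests = corr_test(kin, x, correction=correction, exclude_self=exclude_self)
    # witnesses per eligible edge: target sites of the host whose
    # co-phosphorylation with s is strong and significant
    witnesses = {
        e: {t.other for t in results if abs(t.r) >= delta and t.p_adj < epsilon}
        for e, results in edge_tests.items()
    }
    hosts = {e: kin.host_kinase(e[1]) for e in witnesses}
    # the witness must itself still be credited to the host kinase, so
    # removals propagate: iterate to the (unique, monotone) fixed point
    kept = set(kin.e_ks)
    changed = True
    while changed:
        changed = False
        for e in sorted(witnesses):
            if e not in kept:
                continue
            host = hosts[e]
            if not any((host, s2) in kept for s2 in witnesses[e]):
                kept.discard(e)
                changed = True
    out = kin.restrict(edges=kept | kin.e_sk)
    return prune_singletons(out)


# ---------------------------------------------------------------------------
# PCST edge filter
# ---------------------------------------------------------------------------

def kin_to_pcst_instance(
    kin: KIN, f: Mapping[str, float] | pd.Series, gamma: float = 1.0
) -> PCSTInstance:
    """Undirected projection of a KIN as a PCST instance: each directed
    edge (either orientation) becomes one undirected unit-weight edge;
    substrate nodes are prized |f_s| (0 when f is missing, logged), kinase
    nodes are prized gamma."""
    if isinstance(f, pd.Series):
        f = f.to_dict()
    undirected = {frozenset((a, b)) for a, b in kin.e_ks | kin.e_sk}
    prizes: dict[str, float] = {}
    missing = 0
    for sid in kin.sites:
        if sid in f:
            prizes[sid] = abs(float(f[sid]))
        else:
            prizes[sid] = 0.0
            missing += 1
    for kid in kin.kinases:
        prizes[kid] = float(gamma)
    if missing:
        logger.info("PCST: %d substrate nodes lack a fold change; prize 0", missing)
    nodes = tuple(sorted(kin.node_ids))
    edges = tuple(sorted((min(e), max(e), 1.0) for e in undirected))
    return PCSTInstance(nodes=nodes, edges=edges, prizes=prizes)


def filter_pcst(
    kin: KIN,
    f: Mapping[str, float] | pd.Series,
    gamma: float = 1.0,
    forest: bool = False,
) -> KIN:
    """Prize-collecting Steiner tree edge filter.

    Solves unrooted PCST on the undirected projection and keeps exactly
    the directed edges whose undirected image lies in the solution tree.
    By default a single tree (the best across connected components) is
    returned; ``forest=True`` keeps one tree per component.
    """
    if not kin.node_ids:
        return kin.copy()
    instance = kin_to_pcst_instance(kin, f, gamma=gamma)
    if forest:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(instance.nodes)
        g.add_edges_from((u, v) for u, v, _ in instance.edges)
        keep_nodes: set[str] = set()
        keep_und: set[frozenset[str]] = set()
        for comp in nx.connected_components(g):
            sub = PCSTInstance(
                nodes=tuple(sorted(comp)),
                edges=tuple(e for e in instance.edges if e[0] in comp),
                prizes={v: instance.prizes[v] for v in comp},
            )
            sol = solve_pcst(sub)
            keep_nodes |= set(sol.nodes)
            keep_und |= set(sol.edges)
    else:
        sol = solve_pcst(instance)
        keep_nodes = set(sol.nodes)
        keep_und = set(sol.edges)
    keep_edges = {
        (a, b)
        for a, b in kin.e_ks | kin.e_sk
        if frozenset((a, b)) in keep_und
    }
    out = kin.restrict(
        kinase_ids=set(kin.kinases) & keep_nodes,
        site_ids=set(kin.sites) & keep_nodes,
        edges=keep_edges,
    )
    return prune_singletons(out)
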