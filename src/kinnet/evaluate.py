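"""Randomization-based validation of inferred networks.

The headline question: does a filtered network recover more curated
kinase→site interactions (the reference edge set) than chance? Two null
models answer it from different angles:

* random filtering — draw as many edges as the filtered network kept,
  uniformly without replacement from the baseline's kinase→site edges;
  the overlap distribution reflects what unguided filtering achieves.
* degree-preserving rewiring — shuffle the filtered network's
  kinase→site edges by double-edge swaps that keep every kinase's
  out-degree and every site's in-degree, and the kinase→substrate
  direction, intact; the distribution reflects networks with the same
  hubs but scrambled specific links.

Observed overlaps are compared to each null with a one-sided Z-test
(alternative: observed larger). A hyperparameter sweep runs the pipeline
over a grid and BH-adjusts the resulting P-values per null kind.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import KIN, ReferenceEdgeSet
from .filters import filter_diff, filter_fs, filter_pcst

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullDistribution:
    """Replicate overlap counts from one randomization scheme."""

    replicates: tuple[int, ...]
    kind: str  # RANDOM_FILTER or REWIRE
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0


@dataclass(frozen=True)
class ZTestResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    degenerate: bool = False


def overlap(kin: KIN, ref: ReferenceEdgeSet, protein_level: bool = False) -> int:
    """|E_KS ∩ reference|. Site→kinase edges are never counted.

    ``protein_level`` relaxes matching from (kinase, site) to
    (kinase, protein) for sparse references.
    """
    if not protein_level:
        return len(kin.e_ks & ref.edges)
    mine = {(k, s.rsplit("_", 1)[0]) for k, s in kin.e_ks}
    theirs = {(k, s.rsplit("_", 1)[0]) for k, s in ref.edges}
    return len(mine & theirs)


def random_filter_null(
    baseline: KIN,
    target_size: int,
    ref: ReferenceEdgeSet,
    reps: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Overlap distribution of ``target_size`` edges drawn uniformly
    without replacement from the baseline's kinase→site edges."""
    edges = sorted(baseline.e_ks)
    if target_size > len(edges):
        raise ValueError(
            f"target size {target_size} exceeds baseline KS edge count {len(edges)}"
        )
    rng = np.random.default_rng(seed)
    in_ref = np.array([e in ref.edges for e in edges])
    counts = [
        int(in_ref[rng.choice(len(edges), size=target_size, replace=False)].sum())
        for _ in range(reps)
    ]
    return NullDistribution(tuple(counts), "RANDOM_FILTER", seed)


def _double_edge_swaps(
    edges: list[tuple[str, str]], rng: np.random.Generator, attempts: int
) -> list[tuple[str, str]]:
    """Degree-preserving rewiring of a directed bipartite edge list.

    Each attempt picks two edges (k1,s1), (k2,s2) and swaps targets to
    (k1,s2), (k2,s1) unless that would create a duplicate edge. Kinase
    out-degrees, site in-degrees and edge direction are all preserved.
    """
    edges = list(edges)
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return edges
    idx = rng.integers(0, m, size=(attempts, 2))
    for i, j in idx:
        if i == j:
            continue
        k1, s1 = edges[i]
        k2, s2 = edges[j]
        if k1 == k2 or s1 == s2:
            continue
        e1, e2 = (k1, s2), (k2, s1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((k1, s1))
        edge_set.discard((k2, s2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
    return edges


def rewire_null(
    kin: KIN,
    ref: ReferenceEdgeSet,
    reps: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 100,
) -> NullDistribution:
    """Overlap distribution of degree-preserving rewirings of the
    network's kinase→site edges (``swaps_per_edge * |E|`` attempted
    double-edge swaps per replicate)."""
    edges = sorted(kin.e_ks)
    rng = np.random.default_rng(seed)
    attempts = swaps_per_edge * len(edges)
    logger.info("rewire null: %d attempted swaps per replicate", attempts)
    counts = []
    for _ in range(reps):
        rewired = _double_edge_swaps(edges, rng, attempts)
        counts.append(sum(e in ref.edges for e in rewired))
    return NullDistribution(tuple(counts), "REWIRE", seed)


def z_test_upper(observed: int, null: NullDistribution) -> ZTestResult:
    """One-sided Z-test of the observed overlap against a null
    distribution (alternative: observed is larger). Sample (n−1) standard
    deviation; P = 1 − Φ(z)."""
    mean, sd = null.mean, null.sd
    if sd == 0:
        if observed > mean:
            p, z = 0.0, np.inf
        elif observed < mean:
            p, z = 1.0, -np.inf
        else:
            p, z = 0.5, 0.0
        logger.warning("degenerate null distribution (sd = 0)")
        return ZTestResult(observed, mean, sd, float(z), p, degenerate=True)
    z = (observed - mean) / sd
    return ZTestResult(observed, mean, sd, float(z), float(stats.norm.sf(z)))


def evaluate_kin(
    kin: KIN,
    baseline: KIN,
    ref: ReferenceEdgeSet,
    reps: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 100,
) -> dict:
    """Full evaluation of one filtered network against one reference:
    observed overlap plus both null-model Z-tests."""
    obs = overlap(kin, ref)
    rf = random_filter_null(baseline, len(kin.e_ks), ref, reps=reps, seed=seed)
    rw = rewire_null(kin, ref, reps=reps, seed=seed + 1, swaps_per_edge=swaps_per_edge)
    return {
        "overlap": obs,
        "n_edges": len(kin.e_ks),
        "random_filter": z_test_upper(obs, rf),
        "rewire": z_test_upper(obs, rw),
    }


def sweep(
    sites,
    pssms,
    backgrounds,
    ref: ReferenceEdgeSet,
    fscores=None,
    foldchanges=None,
    grid: dict[str, list] | None = None,
    use_pcst: bool = False,
    reps: int = 200,
    seed: int = 0,
    kinase_accessions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hyperparameter sweep over {alpha, n, beta, gamma}.

    For every grid point the baseline is rebuilt, the requested filters
    applied (FS when ``fscores`` given, DIFF when ``foldchanges`` given,
    optionally PCST), and the filtered network evaluated against both
    nulls. P-values are BH-adjusted across the grid per null kind.
    """
    from .baseline import build_baseline_kin

    grid = grid or {}
    defaults = {"alpha": 0.9, "n": 15, "beta": 0.4, "gamma": 1.0}
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)) if keys else [()]:
        params = dict(defaults)
        params.update(dict(zip(keys, combo)))
        base = build_baseline_kin(
            sites, pssms, backgrounds, n=int(params["n"]), alpha=params["alpha"],
            kinase_accessions=kinase_accessions,
        )
        kin = base
        if fscores is not None:
            kin = filter_fs(kin, fscores, beta=params["beta"])
        if foldchanges is not None:
            kin = filter_diff(kin, foldchanges, gamma=params["gamma"])
        if use_pcst and foldchanges is not None:
            kin = filter_pcst(kin, foldchanges, gamma=params["gamma"])
        res = evaluate_kin(kin, base, ref, reps=reps, seed=seed)
        rows.append(
            {
                **{k: params[k] for k in defaults},
                "n_edges": res["n_edges"],
                "overlap": res["overlap"],
                "p_random_filter": res["random_filter"].p,
                "p_rewire": res["rewire"].p,
            }
        )
    out = pd.DataFrame(rows)
    for col in ("p_random_filter", "p_rewire"):
        out[col + "_adj"] = multipletests(out[col].values, method="fdr_bh")[1]
    return out


def pubmed_coverage(kin: KIN, gene2pubmed: pd.DataFrame) -> pd.DataFrame:
    """Literature-bias profile: distinct PubMed IDs indexed to each target
    protein in the network (proteins hosting its substrate sites).

    ``gene2pubmed`` needs columns ``gene`` (protein/gene id) and ``pmid``.
    Proteins absent from the table get count 0 (logged).
    """
    targets = sorted({kin.sites[s].protein for _, s in kin.e_ks})
    counts = (
        gene2pubmed.drop_duplicates(subset=["gene", "pmid"])
        .groupby("gene")["pmid"]
        .nunique()
    )
    absent = sum(1 for t in targets if t not in counts.index)
    if absent:
        logger.info("pubmed coverage: %d target proteins absent from the table", absent)
    return pd.DataFrame(
        {"protein": targets, "n_pubmed": [int(counts.get(t, 0)) for t in targets]}
    )
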