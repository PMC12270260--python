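"""Shared fixtures: tiny hand-built networks and a random-KIN generator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kinnet.model import KIN, Kinase, KinaseType, Site


def make_random_kin(
    rng: np.random.Generator,
    n_kinases: int = 8,
    n_sites: int = 20,
    edge_prob: float = 0.25,
    hosted_fraction: float = 0.25,
) -> KIN:
    """A random, invariant-respecting KIN: random compatible kinase→site
    edges, with a fraction of sites hosted on kinase proteins (yielding
    site→kinase edges)."""
    kin = KIN()
    kinases = []
    for i in range(n_kinases):
        ktype = KinaseType.SER_THR if i % 2 == 0 or i < n_kinases // 2 else KinaseType.TYR
        k = Kinase(id=f"K{i:02d}", ktype=ktype)
        kin.add_kinase(k)
        kinases.append(k)
    sites = []
    for j in range(n_sites):
        if rng.random() < hosted_fraction:
            host = kinases[int(rng.integers(n_kinases))]
            residue = "S" if host.ktype is KinaseType.SER_THR else "Y"
            site = Site(host.id, 10 + j, residue, "")
        else:
            residue = str(rng.choice(["S", "T", "Y"]))
            site = Site(f"P{j:03d}", 10, residue, "")
        kin.add_site(site)
        sites.append(site)
    for k in kinases:
        for s in sites:
            if k.targets_residue(s.residue) and rng.random() < edge_prob:
                kin.add_edge_ks(k.id, s.id, score=float(rng.uniform(0, 100)),
                                percentile=float(rng.uniform()))
    for s in sites:
        if s.protein in kin.kinases and kin.kinases[s.protein].targets_residue(s.residue):
            kin.add_edge_sk(s.id, s.protein)
    return kin


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def random_kin(rng) -> KIN:
    return make_random_kin(rng)


@pytest.fixture
def tiny_kin() -> KIN:
    """Two kinases, three sites, one hosted site."""
    kin = KIN()
    kin.add_kinase(Kinase("KA", KinaseType.SER_THR))
    kin.add_kinase(Kinase("KB", KinaseType.TYR))
    s1 = Site("P001", 10, "S", "")
    s2 = Site("P002", 20, "Y", "")
    s3 = Site("KA", 30, "S", "")  # site on kinase KA
    for s in (s1, s2, s3):
        kin.add_site(s)
    kin.add_edge_ks("KA", s1.id, score=2.0, percentile=0.95)
    kin.add_edge_ks("KB", s2.id, score=1.5, percentile=0.92)
    kin.add_edge_ks("KA", s3.id, score=3.0, percentile=0.99)
    kin.add_edge_sk(s3.id, "KA")
    return kin


def random_intensities(
    rng: np.random.Generator, site_ids: list[str], n_samples: int = 8
) -> pd.DataFrame:
    return pd.DataFrame(
        2.0 ** rng.normal(20, 1, size=(n_samples, len(site_ids))),
        index=[f"r{i}" for i in range(n_samples)],
        columns=site_ids,
    )
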