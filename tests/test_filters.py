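"""Filter semantics and algebra: boundaries, subgraph/idempotence
properties, commutation, monotonicity, CORR eligibility, PCST tree shape."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from kinnet.filters import filter_corr, filter_diff, filter_fs, filter_pcst
from kinnet.model import KIN, Kinase, KinaseType, Site
from conftest import make_random_kin, random_intensities


def random_scores(rng, kin):
    return {sid: float(rng.uniform()) for sid in kin.sites}


def random_fc(rng, kin):
    return {sid: float(rng.normal(0, 1.5)) for sid in kin.sites}


def is_subgraph(sub: KIN, sup: KIN) -> bool:
    return (
        set(sub.kinases) <= set(sup.kinases)
        and set(sub.sites) <= set(sup.sites)
        and sub.e_ks <= sup.e_ks
        and sub.e_sk <= sup.e_sk
    )


class TestFS:
    def test_boundary_is_inclusive(self, tiny_kin):
        g = {sid: 0.4 for sid in tiny_kin.sites}
        out = filter_fs(tiny_kin, g, beta=0.4)
        assert set(out.sites) == set(tiny_kin.sites)

    def test_all_below_threshold_empties_network(self, tiny_kin):
        g = {sid: 0.1 for sid in tiny_kin.sites}
        out = filter_fs(tiny_kin, g, beta=0.4)
        assert not out.sites and not out.kinases

    def test_beta_zero_keeps_all_scored_sites(self, tiny_kin):
        g = {sid: 0.0 for sid in tiny_kin.sites}
        out = filter_fs(tiny_kin, g, beta=0.0)
        assert set(out.sites) == set(tiny_kin.sites)

    def test_unscored_sites_removed_unless_flagged(self, tiny_kin):
        g = {"P001_S10": 0.9}
        assert set(filter_fs(tiny_kin, g).sites) == {"P001_S10"}
        kept = filter_fs(tiny_kin, g, keep_unscored=True)
        assert set(kept.sites) == set(tiny_kin.sites)

    def test_score_outside_unit_interval_rejected(self, tiny_kin):
        with pytest.raises(ValueError):
            filter_fs(tiny_kin, {"P001_S10": 1.5})


class TestDIFF:
    def test_absolute_value_and_boundary(self, tiny_kin):
        f = {"P001_S10": -1.2, "P002_Y20": 0.99, "KA_S30": 1.0}
        out = filter_diff(tiny_kin, f, gamma=1.0)
        assert set(out.sites) == {"P001_S10", "KA_S30"}

    def test_every_kept_site_is_differential(self, rng):
        for _ in range(5):
            kin = make_random_kin(rng)
            f = random_fc(rng, kin)
            out = filter_diff(kin, f, gamma=1.0)
            assert all(abs(f[sid]) >= 1.0 for sid in out.sites)

    def test_sites_without_foldchange_removed(self, tiny_kin):
        out = filter_diff(tiny_kin, {"P001_S10": 2.0}, gamma=1.0)
        assert set(out.sites) == {"P001_S10"}


class TestFilterAlgebra:
    """Shared contracts: subgraph map, idempotence, FS/DIFF commutation,
    monotone thresholds."""

    N_RANDOM = 100

    def test_subgraph_idempotent_commute_on_random_kins(self):
        rng = np.random.default_rng(7)
        for _ in range(self.N_RANDOM):
            kin = make_random_kin(rng, n_kinases=6, n_sites=12)
            g = random_scores(rng, kin)
            f = random_fc(rng, kin)
            fs = filter_fs(kin, g)
            diff = filter_diff(kin, f)
            pcst = filter_pcst(kin, f)
            for out in (fs, diff, pcst):
                assert is_subgraph(out, kin)
            assert filter_fs(fs, g) == fs
            assert filter_diff(diff, f) == diff
            assert filter_pcst(pcst, f) == pcst
            assert filter_diff(fs, f) == filter_fs(diff, g)

    def test_corr_subgraph_and_idempotent_on_random_kins(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            kin = make_random_kin(rng, n_kinases=6, n_sites=12, hosted_fraction=0.5)
            x = random_intensities(rng, sorted(kin.sites))
            out = filter_corr(kin, x)
            assert is_subgraph(out, kin)
            assert filter_corr(out, x) == out

    def test_raising_thresholds_never_enlarges_output(self, rng):
        kin = make_random_kin(rng)
        g = random_scores(rng, kin)
        f = random_fc(rng, kin)
        for lo, hi in [(0.2, 0.6), (0.5, 0.9)]:
            assert is_subgraph(filter_fs(kin, g, beta=hi), filter_fs(kin, g, beta=lo))
            assert is_subgraph(filter_diff(kin, f, gamma=hi), filter_diff(kin, f, gamma=lo))


def chain_kin() -> KIN:
    """k1 -> s (site on kinase k2), k2 -> {t1, t2}: the CORR-eligible
    motif (phosphorylation of s may drive k2's activity on t1/t2)."""
    kin = KIN()
    kin.add_kinase(Kinase("k1", KinaseType.SER_THR))
    kin.add_kinase(Kinase("k2", KinaseType.SER_THR))
    s = Site("k2", 10, "S", "")
    t1 = Site("PA", 5, "S", "")
    t2 = Site("PB", 6, "T", "")
    for site in (s, t1, t2):
        kin.add_site(site)
    kin.add_edge_ks("k1", s.id)
    kin.add_edge_ks("k2", t1.id)
    kin.add_edge_ks("k2", t2.id)
    kin.add_edge_sk(s.id, "k2")
    return kin


class TestCORR:
    def test_perfect_correlation_keeps_edge(self, rng):
        kin = chain_kin()
        n = 8
        base = rng.normal(20, 1, n)
        x = pd.DataFrame(
            {
                "k2_S10": 2.0 ** base,
                "PA_S5": 2.0 ** (base * 1.3 + 0.5),  # exact linear relation on log2 scale
                "PB_T6": 2.0 ** rng.normal(20, 1, n),
            }
        )
        out = filter_corr(kin, x)
        assert ("k1", "k2_S10") in out.e_ks

    def test_uncorrelated_targets_remove_edge(self, rng):
        kin = chain_kin()
        x = pd.DataFrame(
            {
                "k2_S10": 2.0 ** rng.normal(20, 1, 9),
                "PA_S5": 2.0 ** rng.normal(20, 1, 9),
                "PB_T6": 2.0 ** rng.normal(20, 1, 9),
            }
        )
        out = filter_corr(kin, x)
        assert ("k1", "k2_S10") not in out.e_ks
        # edges onto non-kinase proteins are untouchable
        assert ("k2", "PA_S5") in out.e_ks and ("k2", "PB_T6") in out.e_ks

    def test_no_kinase_hosted_sites_is_identity(self, rng):
        kin = KIN()
        kin.add_kinase(Kinase("k1", KinaseType.SER_THR))
        site = Site("PX", 3, "S", "")
        kin.add_site(site)
        kin.add_edge_ks("k1", site.id)
        x = random_intensities(rng, [site.id])
        assert filter_corr(kin, x) == kin

    def test_sk_edges_never_removed(self, rng):
        kin = chain_kin()
        x = random_intensities(rng, sorted(kin.sites), n_samples=9)
        out = filter_corr(kin, x)
        assert out.e_sk <= kin.e_sk
        surviving_nodes = out.node_ids
        for s, k in kin.e_sk:
            if s in surviving_nodes and k in surviving_nodes:
                assert (s, k) in out.e_sk

    def test_two_conditions_give_two_networks(self, rng):
        kin = chain_kin()
        x1 = random_intensities(rng, sorted(kin.sites), n_samples=8)
        x0 = random_intensities(rng, sorted(kin.sites), n_samples=8)
        res = filter_corr(kin, (x1, x0))
        assert isinstance(res, tuple) and len(res) == 2
        assert all(is_subgraph(k, kin) for k in res)


class TestPCSTFilter:
    def test_star_keeps_strong_substrate_only(self):
        kin = KIN()
        kin.add_kinase(Kinase("k", KinaseType.SER_THR))
        s1, s2 = Site("PA", 1, "S", ""), Site("PB", 2, "S", "")
        kin.add_site(s1)
        kin.add_site(s2)
        kin.add_edge_ks("k", s1.id)
        kin.add_edge_ks("k", s2.id)
        out = filter_pcst(kin, {"PA_S1": 5.0, "PB_S2": 0.01}, gamma=1.0)
        assert out.e_ks == {("k", "PA_S1")}

    def test_zero_prizes_give_empty_network(self, tiny_kin):
        f = {sid: 0.0 for sid in tiny_kin.sites}
        out = filter_pcst(tiny_kin, f, gamma=0.0)
        assert out.n_edges() == 0 and not out.sites

    def test_empty_kin_passes_through(self):
        assert filter_pcst(KIN(), {}).n_edges() == 0

    def test_output_projection_is_a_tree(self, rng):
        for _ in range(20):
            kin = make_random_kin(rng)
            f = random_fc(rng, kin)
            out = filter_pcst(kin, f)
            if out.n_edges() == 0:
                continue
            g = nx.Graph()
            g.add_edges_from(out.e_ks | out.e_sk)
            assert nx.is_tree(g)

    def test_forest_mode_one_tree_per_component(self, rng):
        kin = make_random_kin(rng, n_kinases=6, n_sites=14, edge_prob=0.12)
        f = {sid: 3.0 for sid in kin.sites}
        out = filter_pcst(kin, f, forest=True)
        g = nx.Graph()
        g.add_nodes_from(out.node_ids)
        g.add_edges_from(out.e_ks | out.e_sk)
        assert nx.is_forest(g)
        single = filter_pcst(kin, f, forest=False)
        assert single.n_edges() <= out.n_edges()
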