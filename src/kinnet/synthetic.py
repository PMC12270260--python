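"""Self-contained synthetic phosphoproteomics inputs with planted ground
truth.

The generator emulates the statistical structure the pipeline assumes:

* a toy kinome of PSSMs, each concentrated on a random sequence motif
  (preferred residue weighted ``motif_strength`` : 1, with mild
  log-normal jitter on all entries so scores are continuous), plus
  percentile-calibration backgrounds scored on random flanks;
* a site table in which *planted* sites carry the exact motif of their
  true kinase while decoy sites carry random flanks;
* intensity matrices for two conditions with log-normal noise, planted
  differential sites (condition-1 intensities scaled by
  2**effect_size), and planted co-phosphorylation chains in which the
  phosphosite on a kinase drives that kinase's target sites through a
  shared per-sample latent factor;
* functional scores that are high for planted sites and low for decoys;
* a reference edge set sampled from the planted true edges.

Every site has exactly one true regulating kinase; only the *regulated*
(planted) sites carry that kinase's motif, so the kinome signal available
to PSSM scoring scales with ``motif_strength`` while the ground truth's
site coverage stays uniform — at strength 1 the pipeline's overlap with
the truth is indistinguishable from chance by construction.

Defaults give a small but realistic study: 24 + 8 kinases, 160 sites
(one quarter regulated), 6 samples per condition (a typical replicate
count for a perturbation phosphoproteomics screen), log2 effect size 2,
noise sd 0.25 on the log2 scale, 5% missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import OFFSETS, PSSM, BackgroundScores, compute_background, write_backgrounds, write_pssms
from .model import AMINO_ACIDS, KinaseType, ReferenceEdgeSet, Site, write_reference_edges, write_site_table
from .quantify import write_foldchanges, write_intensities

FLANK_LEN = 11  # phosphoacceptor at index 5
_CENTER = FLANK_LEN // 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study."""

    seed: int = 0
    n_st_kinases: int = 24
    n_tyr_kinases: int = 8
    n_sites: int = 160
    n_background_sites: int = 200
    motif_strength: float = 10.0
    weight_jitter_sd: float = 0.1
    planted_fraction: float = 0.25
    n_samples: int = 6
    effect_size: float = 2.0
    n_diff_sites: int = 40
    n_chains: int = 4
    noise_sd: float = 0.25
    chain_noise_sd: float = 0.05
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.motif_strength < 1:
            raise ValueError("motif strength must be >= 1 (1 = uninformative)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


@dataclass
class GroundTruth:
    """What was planted: true edges, differential sites, chains, motifs."""

    true_edges: set[tuple[str, str]] = field(default_factory=set)
    diff_sites: dict[str, float] = field(default_factory=dict)
    chains: list[tuple[str, str, list[str]]] = field(default_factory=list)  # (kinase, host site, targets)
    motifs: dict[str, dict[int, str]] = field(default_factory=dict)


@dataclass
class SyntheticData:
    spec: SyntheticSpec
    pssms: dict[str, PSSM]
    backgrounds: dict[str, BackgroundScores]
    sites: list[Site]
    x1: pd.DataFrame
    x0: pd.DataFrame
    fscores: pd.Series
    truth: GroundTruth


def _random_flank(rng: np.random.Generator, residue: str) -> str:
    aas = rng.choice(list(AMINO_ACIDS), size=FLANK_LEN)
    aas[_CENTER] = residue
    return "".join(aas)


def _motif_flank(motif: dict[int, str], residue: str, rng: np.random.Generator) -> str:
    flank = list(_random_flank(rng, residue))
    for o, aa in motif.items():
        flank[_CENTER + o] = aa
    return "".join(flank)


def make_toy_kinome(
    spec: SyntheticSpec,
) -> tuple[dict[str, PSSM], dict[str, BackgroundScores], GroundTruth]:
    """Generate PSSMs with planted motifs and their calibration
    backgrounds. Deterministic under ``spec.seed``."""
    kinome_seed, bg_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(kinome_seed)
    truth = GroundTruth()
    pssms: dict[str, PSSM] = {}
    plan = [(KinaseType.SER_THR, "KST", spec.n_st_kinases),
            (KinaseType.TYR, "KTY", spec.n_tyr_kinases)]
    for ktype, prefix, count in plan:
        offsets = OFFSETS[ktype]
        if count > len(AMINO_ACIDS) ** len(offsets):
            raise ValueError(f"cannot plant {count} distinct motifs over {len(offsets)} offsets")
        used: set[tuple[str, ...]] = set()
        for i in range(count):
            kid = f"{prefix}{i:02d}"
            while True:
                motif = {o: rng.choice(list(AMINO_ACIDS)) for o in offsets}
                key = tuple(motif[o] for o in offsets)
                if key not in used:
                    used.add(key)
                    break
            truth.motifs[kid] = motif
            weights = {}
            for o in offsets:
                jitter = np.exp(rng.normal(0.0, spec.weight_jitter_sd, size=len(AMINO_ACIDS)))
                for j, aa in enumerate(AMINO_ACIDS):
                    w = float(jitter[j])
                    if aa == motif[o]:
                        w *= spec.motif_strength
                    weights[(o, aa)] = w
            pssms[kid] = PSSM(kinase_id=kid, ktype=ktype, offsets=offsets, weights=weights)
    bg_rng = np.random.default_rng(bg_seed)
    bg_flanks = {
        KinaseType.SER_THR: [
            _random_flank(bg_rng, bg_rng.choice(["S", "T"]))
            for _ in range(spec.n_background_sites)
        ],
        KinaseType.TYR: [
            _random_flank(bg_rng, "Y") for _ in range(spec.n_background_sites)
        ],
    }
    backgrounds = {
        kid: compute_background(p, bg_flanks[p.ktype]) for kid, p in pssms.items()
    }
    return pssms, backgrounds, truth


def make_sites_and_intensities(
    spec: SyntheticSpec,
    pssms: dict[str, PSSM],
    truth: GroundTruth,
) -> SyntheticData:
    """Generate the site table, intensity matrices, functional scores and
    complete ground truth for a kinome from :func:`make_toy_kinome`."""
    # children 0 and 1 of the root seed belong to the kinome generator
    site_seed, intens_seed, score_seed = np.random.SeedSequence(spec.seed).spawn(5)[2:]
    rng = np.random.default_rng(site_seed)
    st_kinases = sorted(k for k, p in pssms.items() if p.ktype is KinaseType.SER_THR)
    ty_kinases = sorted(k for k, p in pssms.items() if p.ktype is KinaseType.TYR)

    # every site has exactly one true regulating kinase; only *regulated*
    # (planted) sites carry that kinase's motif in their flank, so the
    # recoverable signal scales with motif strength while the truth's site
    # coverage stays uniform
    sites: list[Site] = []
    planted: list[str] = []
    planted_of: dict[str, list[str]] = {}
    n_planted = int(round(spec.planted_fraction * spec.n_sites))
    for i in range(spec.n_sites):
        prot = f"PR{i:04d}"
        if ty_kinases and rng.random() < len(ty_kinases) / max(
            1, len(ty_kinases) + len(st_kinases)
        ):
            kid = ty_kinases[int(rng.integers(len(ty_kinases)))]
            residue = "Y"
        else:
            kid = st_kinases[int(rng.integers(len(st_kinases)))]
            residue = str(rng.choice(["S", "T"]))
        if i < n_planted:
            flank = _motif_flank(truth.motifs[kid], residue, rng)
            planted.append(f"{prot}_{residue}10")
            planted_of.setdefault(kid, []).append(f"{prot}_{residue}10")
        else:
            flank = _random_flank(rng, residue)
        site = Site(prot, 10, residue, flank)
        truth.true_edges.add((kid, site.id))
        sites.append(site)

    # co-phosphorylation chains: a phosphosite hosted on a kinase protein
    # drives the intensity columns of that kinase's motif-backed targets
    # (the targets that actually enter the baseline network)
    chain_kinases = [k for k in st_kinases if planted_of.get(k)][: spec.n_chains]
    chain_members: dict[str, list[str]] = {}
    for j, kid in enumerate(chain_kinases):
        driver = st_kinases[(j + 1) % len(st_kinases)]
        host = Site(kid, 10, "S", _motif_flank(truth.motifs[driver], "S", rng))
        truth.true_edges.add((driver, host.id))
        sites.append(host)
        planted.append(host.id)
        targets = sorted(planted_of[kid])
        truth.chains.append((kid, host.id, targets))
        chain_members[host.id] = targets

    # differential sites are drawn from the planted (truly regulated) ones
    diff_ids = rng.choice(planted, size=min(spec.n_diff_sites, len(planted)), replace=False)
    for sid in diff_ids:
        truth.diff_sites[str(sid)] = float(spec.effect_size * rng.choice([-1.0, 1.0]))

    # intensities: log-normal noise around a per-site baseline; condition 1
    # shifted by the planted effect; chain members share a latent factor
    irng = np.random.default_rng(intens_seed)
    ids = [s.id for s in sites]
    mu = pd.Series(irng.normal(20.0, 1.0, size=len(ids)), index=ids)
    in_chain: dict[str, str] = {}
    for host, targets in chain_members.items():
        in_chain[host] = host
        for t in targets:
            in_chain[t] = host
    n = spec.n_samples
    latents = {
        (host, cond): irng.normal(0.0, 1.0, size=n)
        for host in chain_members
        for cond in (0, 1)
    }
    mats = {}
    for cond in (0, 1):
        cols = {}
        for sid in ids:
            eff = truth.diff_sites.get(sid, 0.0) if cond == 1 else 0.0
            if sid in in_chain:
                z = latents[(in_chain[sid], cond)]
                log2x = mu[sid] + eff + z + irng.normal(0.0, spec.chain_noise_sd, size=n)
            else:
                log2x = mu[sid] + eff + irng.normal(0.0, spec.noise_sd, size=n)
            cols[sid] = 2.0 ** log2x
        m = pd.DataFrame(cols, index=[f"c{cond}_r{i}" for i in range(n)])
        if spec.missing_rate > 0:
            mask = irng.random(m.shape) < spec.missing_rate
            m = m.mask(mask)
        mats[cond] = m

    srng = np.random.default_rng(score_seed)
    fscores = pd.Series(
        {
            s.id: (srng.uniform(0.5, 1.0) if s.id in set(planted) else srng.uniform(0.0, 0.35))
            for s in sites
        }
    )
    return SyntheticData(
        spec=spec,
        pssms=pssms,
        backgrounds={},
        sites=sites,
        x1=mats[1],
        x0=mats[0],
        fscores=fscores,
        truth=truth,
    )


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Full synthetic study: kinome + sites + intensities + truth."""
    pssms, backgrounds, truth = make_toy_kinome(spec)
    data = make_sites_and_intensities(spec, pssms, truth)
    data.backgrounds = backgrounds
    return data


def make_reference(
    truth: GroundTruth, fraction_known: float = 1.0, seed: int = 0
) -> ReferenceEdgeSet:
    """Sample a fraction of the planted true edges as the 'known'
    reference, standing in for a curated interaction database."""
    if not 0 <= fraction_known <= 1:
        raise ValueError("fraction_known must be in [0, 1]")
    edges = sorted(truth.true_edges)
    k = int(round(fraction_known * len(edges)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges), size=k, replace=False) if k else []
    return ReferenceEdgeSet(edges=frozenset(edges[i] for i in chosen))


def write_dataset(spec: SyntheticSpec, outdir: str | Path, fraction_known: float = 1.0) -> SyntheticData:
    """Generate a study and write every artifact as TSV files:
    sites.tsv, pssm.tsv, bg.tsv, x1.tsv, x0.tsv, fscores.tsv, fc_true.tsv,
    truth_edges.tsv, reference.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate(spec)
    write_site_table(data.sites, outdir / "sites.tsv")
    write_pssms(data.pssms, outdir / "pssm.tsv")
    write_backgrounds(data.backgrounds, outdir / "bg.tsv")
    write_intensities(data.x1, outdir / "x1.tsv")
    write_intensities(data.x0, outdir / "x0.tsv")
    pd.DataFrame({"id": data.fscores.index, "score": data.fscores.values}).to_csv(
        outdir / "fscores.tsv", sep="\t", index=False
    )
    write_foldchanges(
        pd.Series({s.id: data.truth.diff_sites.get(s.id, 0.0) for s in data.sites}),
        outdir / "fc_true.tsv",
    )
    pd.DataFrame(sorted(data.truth.true_edges), columns=["kinase", "site"]).to_csv(
        outdir / "truth_edges.tsv", sep="\t", index=False
    )
    write_reference_edges(
        make_reference(data.truth, fraction_known=fraction_known, seed=spec.seed),
        outdir / "reference.tsv",
    )
    return data
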