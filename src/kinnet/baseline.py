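"""Baseline kinase interaction network construction.

Each kinase carries a position-specific scoring matrix (PSSM) over the
flanking positions of its substrate motif. A site's raw match score for a
kinase is the product of the matrix entries selected by the flank; the
score is calibrated into a percentile against a background distribution of
scores over a curated reference site set. For every measured site, the top
``n`` kinases of the compatible specificity class with percentile at least
``alpha`` (defaults n=15, alpha=0.9) contribute kinase→site edges; sites
located on a kinase additionally contribute a site→kinase edge. The result
is the condition-agnostic supergraph that all downstream filters act on.

Serine/threonine PSSMs span 9 flank positions (offsets −5…+4), tyrosine
PSSMs span 10 (−5…+5), the phosphoacceptor itself excluded.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import (
    AMINO_ACIDS,
    KIN,
    Kinase,
    KinaseType,
    PAD,
    ParseError,
    Site,
    prune_singletons,
    read_kin,
)

logger = logging.getLogger(__name__)

#: flank offsets covered by each PSSM class (phosphoacceptor at 0 excluded)
OFFSETS = {
    KinaseType.SER_THR: tuple(o for o in range(-5, 5) if o != 0),
    KinaseType.TYR: tuple(o for o in range(-5, 6) if o != 0),
}


@dataclass(frozen=True)
class PSSM:
    """Per-kinase position × residue weight matrix.

    ``weights[(offset, aa)]`` is a positive multiplicative preference for
    amino acid ``aa`` at flank position ``offset`` relative to the
    phosphoacceptor.
    """

    kinase_id: str
    ktype: KinaseType
    offsets: tuple[int, ...]
    weights: dict[tuple[int, str], float]

    def __post_init__(self) -> None:
        for o in self.offsets:
            for aa in AMINO_ACIDS:
                w = self.weights.get((o, aa))
                if w is None:
                    raise ValueError(
                        f"PSSM {self.kinase_id}: missing weight for ({o}, {aa})"
                    )
                if w <= 0:
                    raise ValueError(
                        f"PSSM {self.kinase_id}: non-positive weight at ({o}, {aa})"
                    )


@dataclass(frozen=True)
class BackgroundScores:
    """Reference score distribution of one kinase over the curated
    background site set of its class, stored sorted ascending."""

    kinase_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"empty background for kinase {self.kinase_id}")
        if any(a > b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError(f"background for {self.kinase_id} is not sorted")


def score_site(pssm: PSSM, flank: str) -> float:
    """Raw PSSM match score: product of weights at every covered offset.

    Offsets that fall on ``_`` padding contribute a neutral factor of 1, so
    sites near protein termini are scored on the residues that exist.
    """
    center = len(flank) // 2
    score = 1.0
    for o in pssm.offsets:
        pos = center + o
        if pos < 0 or pos >= len(flank):
            continue
        aa = flank[pos]
        if aa == PAD:
            continue
        if aa not in AMINO_ACIDS:
            raise ValueError(f"flank {flank!r}: invalid character {aa!r} at offset {o}")
        score *= pssm.weights[(o, aa)]
    return score


def percentile(score: float, bg: BackgroundScores) -> float:
    """Fraction of the background distribution not exceeding *score*."""
    return bisect_right(bg.scores, score) / len(bg.scores)


def select_kinases(
    site: Site,
    pssms: dict[str, PSSM],
    backgrounds: dict[str, BackgroundScores],
    n: int = 15,
    alpha: float = 0.9,
) -> list[tuple[str, float, float]]:
    """Rank compatible kinases for one site and apply the top-n / alpha cut.

    Returns at most ``n`` tuples ``(kinase_id, score, percentile)`` sorted
    non-increasing by percentile, every percentile ≥ alpha. Ties in
    percentile are broken by raw score (descending), then kinase id.
    """
    ktype = site.ktype
    scored = []
    for kid, pssm in pssms.items():
        if pssm.ktype is not ktype:
            continue
        if kid not in backgrounds:
            raise KeyError(f"no background score set for kinase {kid}")
        r = score_site(pssm, site.flank)
        p = percentile(r, backgrounds[kid])
        scored.append((kid, r, p))
    scored.sort(key=lambda t: (-t[2], -t[1], t[0]))
    top = scored[:n]
    return [(kid, r, p) for kid, r, p in top if p >= alpha]


def build_baseline_kin(
    sites: list[Site],
    pssms: dict[str, PSSM],
    backgrounds: dict[str, BackgroundScores],
    n: int = 15,
    alpha: float = 0.9,
    kinase_accessions: dict[str, str] | None = None,
) -> KIN:
    """Construct the baseline KIN from measured sites and the kinome.

    Kinase→site edges are selected per specificity class and unioned;
    site→kinase edges link each measured site to the kinase (of matching
    class) whose protein hosts it. Kinase identity and site accessions are
    matched through ``kinase_accessions`` (identity map by default).
    Singletons are pruned from the result.
    """
    kin = KIN()
    accmap = kinase_accessions or {}
    for kid, pssm in pssms.items():
        kin.add_kinase(Kinase(id=kid, ktype=pssm.ktype), accession=accmap.get(kid, kid))
    acc_to_kinase = {kin.accession_of[kid]: kid for kid in kin.kinases}

    have_types = {p.ktype for p in pssms.values()}
    unpssmed = 0
    for site in sites:
        kin.add_site(site)
        if site.flank and all(c == PAD for c in site.flank):
            logger.warning("site %s has an all-padding flank; scored neutrally", site.id)
        if site.ktype not in have_types:
            unpssmed += 1
            continue
        for kid, r, p in select_kinases(site, pssms, backgrounds, n=n, alpha=alpha):
            kin.add_edge_ks(kid, site.id, score=r, percentile=p)
    if unpssmed:
        logger.warning(
            "%d sites had a residue type with no PSSMs; retained only if "
            "they gain a substrate-kinase edge",
            unpssmed,
        )
    # substrate-kinase edges: measured sites located on a kinase of the
    # matching specificity class
    for site in sites:
        kid = acc_to_kinase.get(site.protein)
        if kid is not None and kin.kinases[kid].ktype is site.ktype:
            kin.add_edge_sk(site.id, kid)
    return prune_singletons(kin)


def import_baseline(path: str | Path) -> KIN:
    """Load a user-provided baseline network from an edge-list TSV.

    Residue/kinase-type compatibility is validated on read; incompatible
    rows raise a parse error naming them.
    """
    kin = read_kin(path)
    kin.validate()
    return kin


# ---------------------------------------------------------------------------
# kinome IO
# ---------------------------------------------------------------------------

def read_pssms(path: str | Path) -> dict[str, PSSM]:
    """Read PSSMs from long-by-offset TSV: columns kinase, ktype, offset,
    then one column per amino acid."""
    df = pd.read_csv(path, sep="\t")
    missing = {"kinase", "ktype", "offset"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    pssms: dict[str, PSSM] = {}
    for kid, grp in df.groupby("kinase", sort=True):
        ktype = KinaseType(grp["ktype"].iloc[0])
        offsets = tuple(sorted(int(o) for o in grp["offset"]))
        weights: dict[tuple[int, str], float] = {}
        for _, row in grp.iterrows():
            for aa in AMINO_ACIDS:
                weights[(int(row["offset"]), aa)] = float(row[aa])
        pssms[str(kid)] = PSSM(kinase_id=str(kid), ktype=ktype, offsets=offsets, weights=weights)
    return pssms


def write_pssms(pssms: dict[str, PSSM], path: str | Path) -> None:
    rows = []
    for kid in sorted(pssms):
        p = pssms[kid]
        for o in p.offsets:
            row = {"kinase": kid, "ktype": p.ktype.value, "offset": o}
            row.update({aa: p.weights[(o, aa)] for aa in AMINO_ACIDS})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_backgrounds(path: str | Path) -> dict[str, BackgroundScores]:
    """Read background score sets from long TSV (columns kinase, score)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, BackgroundScores] = {}
    for kid, grp in df.groupby("kinase", sort=True):
        out[str(kid)] = BackgroundScores(
            kinase_id=str(kid), scores=tuple(sorted(float(s) for s in grp["score"]))
        )
    return out


def write_backgrounds(backgrounds: dict[str, BackgroundScores], path: str | Path) -> None:
    rows = [
        {"kinase": kid, "score": s}
        for kid in sorted(backgrounds)
        for s in backgrounds[kid].scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compute_background(pssm: PSSM, flanks: list[str]) -> BackgroundScores:
    """Score a reference flank collection with one PSSM to obtain its
    percentile-calibration distribution."""
    return BackgroundScores(
        kinase_id=pssm.kinase_id,
        scores=tuple(sorted(score_site(pssm, f) for f in flanks)),
    )
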