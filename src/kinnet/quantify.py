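"""Per-site log2 fold changes from phosphorylation intensity matrices.

Two estimators are provided. With paired samples (the same biological
replicate measured in both conditions) the fold change of site s is the
mean of per-pair log-ratios:

    f_s = mean_i log2( x1[i,s] / x0[i,s] )

Without pairing it is the log-ratio of condition means:

    f_s = log2( mean_i x1[i,s] / mean_i x0[i,s] )

Matrices are samples × sites; zeros and negative intensities are treated
as missing (no pseudocount is applied). The two estimators coincide when
each condition has a single sample.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _as_matrix(x: pd.DataFrame) -> pd.DataFrame:
    """Coerce to float and mask non-positive intensities as missing."""
    x = x.astype(float)
    n_bad = int((x <= 0).sum().sum())
    if n_bad:
        logger.warning("%d non-positive intensities treated as missing", n_bad)
    return x.where(x > 0)


def log2fc_paired(x1: pd.DataFrame, x0: pd.DataFrame) -> pd.Series:
    """Paired fold changes: mean over complete sample pairs of the per-pair
    log2 ratio. Rows are samples (row i of x1 pairs with row i of x0),
    columns are site ids.

    Sites with no usable pair are omitted with a warning.
    """
    if x1.shape[0] != x0.shape[0]:
        raise ValueError(
            f"paired conditions need equal sample counts, got {x1.shape[0]} and {x0.shape[0]}"
        )
    shared = x1.columns.intersection(x0.columns)
    a = _as_matrix(x1[shared])
    b = _as_matrix(x0[shared]).set_axis(a.index, axis=0)
    ratios = np.log2(a / b)  # NaN wherever either member of a pair is missing
    f = ratios.mean(axis=0, skipna=True)
    dropped = f[f.isna()].index
    if len(dropped):
        logger.warning("%d sites had no usable sample pair and were omitted", len(dropped))
    return f.dropna()


def log2fc_unpaired(x1: pd.DataFrame, x0: pd.DataFrame) -> pd.Series:
    """Unpaired fold changes: log2 ratio of per-condition means over the
    present values. Sites whose control mean is undefined are omitted."""
    shared = x1.columns.intersection(x0.columns)
    m1 = _as_matrix(x1[shared]).mean(axis=0, skipna=True)
    m0 = _as_matrix(x0[shared]).mean(axis=0, skipna=True)
    f = np.log2(m1 / m0)
    dropped = f[f.isna()].index
    if len(dropped):
        logger.warning("%d sites had an undefined condition mean and were omitted", len(dropped))
    return f.dropna()


def log2fc(x1: pd.DataFrame, x0: pd.DataFrame, paired: bool = False) -> pd.Series:
    return log2fc_paired(x1, x0) if paired else log2fc_unpaired(x1, x0)


def validate_foldchanges(f: pd.Series, site_ids: set[str] | list[str]) -> pd.Series:
    """Validate a user-supplied fold-change vector against the measured
    site set: unmeasured ids are dropped with a warning; non-finite values
    raise."""
    bad = f[~np.isfinite(f.astype(float))]
    if len(bad):
        raise ValueError(f"non-finite fold changes for sites: {sorted(bad.index)}")
    site_ids = set(site_ids)
    keep = f.index.isin(site_ids)
    if (~keep).sum():
        logger.warning("%d fold-change entries not in the measured site set dropped",
                       int((~keep).sum()))
    return f[keep].astype(float)


# ---------------------------------------------------------------------------
# IO — intensity matrices are stored sites × samples on disk (first column
# `id`), the transpose of the in-memory samples × sites orientation.
# ---------------------------------------------------------------------------

def read_intensities(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df.T.astype(float)


def write_intensities(x: pd.DataFrame, path: str | Path) -> None:
    out = x.T
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_foldchanges(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["log2fc"].astype(float).values, index=df["id"].astype(str))


def write_foldchanges(f: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"id": f.index, "log2fc": f.values}).to_csv(path, sep="\t", index=False)
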