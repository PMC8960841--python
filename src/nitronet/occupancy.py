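"""Partition OTUs into frequent and rare via the index of dispersion.

The core community is defined distributionally, not by an abundance cutoff: an
OTU is "frequent" when its variance-to-mean ratio across samples, weighted by
occupancy, exceeds what a Poisson (random placement) null allows.  For OTU j

    I_j = (sigma_j^2 / mu_j) * O_j

with mu and sigma^2 the mean and (n-1)-denominator variance of its mean
rarefied abundance across the n samples and O_j the proportion of samples in
which it occurs.  The test statistic D_j = I_j * (n - 1) is referred to the
upper tail of chi^2 with n-1 degrees of freedom — the classical dispersion
test with occupancy folded into the statistic.  Frequent OTUs are those with
Pr(D_j) below alpha; everything else (including all-absent OTUs) is rare.

Abundances are means over repeated rarefactions so that unequal sequencing
depth does not masquerade as overdispersion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rarefy_mean", "dispersion_table", "partition_frequent"]

log = logging.getLogger(__name__)


def rarefy_mean(
    counts: pd.DataFrame,
    depth: int,
    n_reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean of ``n_reps`` rarefactions (subsampling without replacement).

    Each sample is independently subsampled to ``depth`` reads ``n_reps``
    times with its own RNG stream; the element-wise mean is returned.  Samples
    whose total is below ``depth`` are dropped with a warning.  A sample whose
    total equals ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    X = counts.to_numpy(dtype=np.int64)
    totals = X.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(counts.index[~keep])
        log.warning("dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    X = X[keep]
    streams = np.random.SeedSequence(seed).spawn(X.shape[0])
    out = np.empty(X.shape, dtype=float)
    for i, row in enumerate(X):
        if row.sum() == depth:
            out[i] = row
            continue
        rng = np.random.default_rng(streams[i])
        acc = np.zeros(row.shape[0])
        for _ in range(n_reps):
            acc += rng.multivariate_hypergeometric(row, depth)
        out[i] = acc / n_reps
    return pd.DataFrame(out, index=counts.index[keep], columns=counts.columns)


def dispersion_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-OTU dispersion records from a samples x OTUs abundance matrix.

    Returns a DataFrame indexed by OTU with columns ``mean``, ``variance``,
    ``occupancy``, ``index`` (I), ``statistic`` (I*(n-1)) and ``p_value``.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    occ = (X > 0).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        I = np.where(mu > 0, var / np.where(mu > 0, mu, 1.0) * occ, 0.0)
    D = I * (n - 1)
    p = stats.chi2.sf(D, df=n - 1)
    return pd.DataFrame(
        {
            "mean": mu,
            "variance": var,
            "occupancy": occ,
            "index": I,
            "statistic": D,
            "p_value": p,
        },
        index=matrix.columns,
    )


def partition_frequent(
    records: pd.DataFrame,
    n_samples: int,
    alpha: float = 0.05,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split OTUs into (frequent, rare) by the upper-tail chi^2 criterion.

    Frequent: dispersion statistic exceeds the chi^2_{n-1} critical value at
    ``alpha`` (equivalently p_value < alpha).  The two sets are disjoint and
    exhaustive over the index of ``records``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    crit = stats.chi2.isf(alpha, df=n_samples - 1)
    freq = frozenset(records.index[records["statistic"] > crit])
    rare = frozenset(records.index) - freq
    return freq, frozenset(rare)
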