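"""Log-ratio transforms for compositional community data.

Sequencing count tables carry only relative information, so the analyses in
this package operate on log-ratios rather than raw counts.  Three steps are
provided:

* :func:`impute_zeros` — Bayesian-multiplicative replacement of zero counts,
  which leaves the ratios between observed parts untouched;
* :func:`clr_transform` — the centred log-ratio transform, mapping each sample
  onto the hyperplane of zero-sum log abundances;
* :func:`philr_transform` — the phylogenetic isometric log-ratio transform,
  which re-expresses a composition as one "balance" per internal node of a
  rooted binary phylogeny.  A balance contrasts the geometric mean abundance of
  the taxa descending from the node's first child (numerator) against those of
  its second child (denominator); positive values mean the numerator clade is
  relatively more abundant.

The PhILR basis is orthonormal in CLR space, so Euclidean distances between
samples in balance space equal Aitchison distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "Balance",
    "impute_zeros",
    "clr_transform",
    "philr_basis",
    "philr_transform",
]


@dataclass(frozen=True)
class Balance:
    """One internal node of the phylogeny and the tip sets it contrasts."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    @property
    def n_num(self) -> int:
        return len(self.numerator)

    @property
    def n_den(self) -> int:
        return len(self.denominator)


def impute_zeros(counts: pd.DataFrame, prior_strength: str | float = "sqrt") -> pd.DataFrame:
    """Replace zero counts by Bayesian-multiplicative imputation.

    Zeros in sample *i* are replaced by their posterior expectation under a
    uniform Dirichlet prior with total strength ``s_i`` (default the square
    root of the sample total); the non-zero parts are rescaled multiplicatively
    so each sample keeps its original total.  Ratios between non-zero parts are
    therefore preserved exactly.

    Parameters
    ----------
    counts
        samples x parts table of non-negative counts.
    prior_strength
        ``"sqrt"`` for ``s_i = sqrt(N_i)``, or a positive float used for all
        samples.

    Returns
    -------
    DataFrame of strictly positive values with unchanged row sums.
    """
    X = counts.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = list(counts.index[totals <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    n, D = X.shape
    if prior_strength == "sqrt":
        s = np.sqrt(totals)
    else:
        s = float(prior_strength)
        if s <= 0:
            raise ValueError("prior_strength must be positive")
        s = np.full(n, s)
    t = 1.0 / D  # uniform prior proportions
    P = X / totals[:, None]
    zeros = X == 0
    repl = (t * s / (totals + s))[:, None] * np.ones_like(P)
    out = np.where(zeros, repl, 0.0)
    lost = out.sum(axis=1)  # mass given to zeros, taken multiplicatively
    out = out + np.where(zeros, 0.0, P * (1.0 - lost)[:, None])
    # imputed value should stay below the smallest observed proportion
    with np.errstate(invalid="ignore"):
        minpos = np.where(zeros, np.inf, P).min(axis=1)
    if np.any(zeros.any(axis=1) & (t * s / (totals + s) >= minpos)):
        warnings.warn("imputed value not below the minimum observed proportion "
                      "for at least one sample", stacklevel=2)
    return pd.DataFrame(out * totals[:, None], index=counts.index, columns=counts.columns)


def clr_transform(x: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform: ``ln x - mean(ln x)`` per sample (row)."""
    X = x.to_numpy(dtype=float)
    if np.any(X <= 0):
        raise ValueError("clr requires strictly positive entries; impute zeros first")
    L = np.log(X)
    return pd.DataFrame(L - L.mean(axis=1, keepdims=True), index=x.index, columns=x.columns)


def _internal_name(node: TreeNode, idx: int) -> str:
    return node.name if node.name else f"n{idx}"


def philr_basis(tree: TreeNode, parts: list[str]) -> tuple[np.ndarray, list[Balance]]:
    """Orthonormal sequential-binary-partition basis from a rooted binary tree.

    Returns the (parts x balances) contrast matrix ``V`` and the per-node
    :class:`Balance` metadata.  Column ``v`` of ``V`` carries weight
    ``+sqrt(n_R / (n_L (n_L + n_R)))`` on numerator tips and
    ``-sqrt(n_L / (n_R (n_L + n_R)))`` on denominator tips, so
    ``balances = ln(x) @ V``.
    """
    tips = {t.name for t in tree.tips()}
    if tips != set(parts):
        missing = tips.symmetric_difference(parts)
        raise ValueError(f"tree tips and composition parts differ: {sorted(missing)[:5]} ...")
    col = {p: j for j, p in enumerate(parts)}
    internals = [n for n in tree.preorder() if n.children]
    balances: list[Balance] = []
    V = np.zeros((len(parts), len(internals)))
    for i, node in enumerate(internals):
        if len(node.children) != 2:
            raise ValueError(
                f"node {node.name!r} has {len(node.children)} children; tree must be binary"
            )
        left, right = node.children  # first child is the numerator by convention
        num = tuple(t.name for t in ([left] if left.is_tip() else left.tips()))
        den = tuple(t.name for t in ([right] if right.is_tip() else right.tips()))
        nL, nR = len(num), len(den)
        a = np.sqrt(nR / (nL * (nL + nR)))
        b = -np.sqrt(nL / (nR * (nL + nR)))
        for p in num:
            V[col[p], i] = a
        for p in den:
            V[col[p], i] = b
        balances.append(Balance(_internal_name(node, i), num, den))
    return V, balances


def philr_transform(x: pd.DataFrame, tree: TreeNode) -> tuple[pd.DataFrame, list[Balance]]:
    """Phylogenetic ILR transform of a strictly positive composition.

    ``b_v = sqrt(n_L n_R / (n_L + n_R)) * ln(g(x_L) / g(x_R))`` for each
    internal node ``v``, with ``g`` the geometric mean over the tips on each
    side.  Number of balances equals number of tips minus one.
    """
    X = x.to_numpy(dtype=float)
    if np.any(X <= 0):
        raise ValueError("philr requires strictly positive entries; impute zeros first")
    V, balances = philr_basis(tree, list(x.columns))
    B = np.log(X) @ V
    return pd.DataFrame(B, index=x.index, columns=[b.name for b in balances]), balances
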