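"""Observed turnover metrics: abundance-weighted beta-MNTD and Bray-Curtis.

beta-MNTD (beta mean nearest taxon distance) between communities k and m is

    0.5 * [ sum_i f_ik * min_j d(i, j in m)  +  sum_i f_im * min_j d(i, j in k) ]

where f are within-site relative abundances, d is the patristic distance,
and the minimum runs over taxa with positive abundance in the *other*
community.  A taxon shared by both communities finds itself at distance
zero, so identical communities have beta-MNTD 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from .io import CommunityMatrix, Phylogeny

__all__ = [
    "cophenetic",
    "relative_abundances",
    "beta_mntd",
    "bray_curtis",
    "pairwise_beta_mntd",
    "pairwise_bray_curtis",
]


def cophenetic(tree: Phylogeny, order=None) -> pd.DataFrame:
    """Patristic distance matrix of ``tree`` (see :meth:`Phylogeny.cophenetic`)."""
    return tree.cophenetic(order=order)


def relative_abundances(community: CommunityMatrix) -> pd.DataFrame:
    """Site-wise relative abundances; each row sums to one."""
    return community.relative_abundances()


def beta_mntd(f_k: np.ndarray, f_m: np.ndarray, D: np.ndarray) -> float:
    """Abundance-weighted beta mean nearest taxon distance for one pair.

    Parameters
    ----------
    f_k, f_m :
        Abundance vectors of the two communities over a common taxon order
        (raw counts are accepted; they are normalized internally).
    D :
        Square patristic distance matrix in the same taxon order.
    """
    f_k = np.asarray(f_k, dtype=float)
    f_m = np.asarray(f_m, dtype=float)
    ik = np.flatnonzero(f_k > 0)
    im = np.flatnonzero(f_m > 0)
    if ik.size == 0 or im.size == 0:
        raise ValueError("beta_mntd needs both communities non-empty")
    wk = f_k[ik] / f_k[ik].sum()
    wm = f_m[im] / f_m[im].sum()
    sub = D[np.ix_(ik, im)]
    return 0.5 * (wk @ sub.min(axis=1) + wm @ sub.min(axis=0))


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min(x,y)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("bray_curtis needs both communities non-empty")
    return float(_sp_braycurtis(x, y))


def pairwise_beta_mntd(community: CommunityMatrix, coph: pd.DataFrame) -> pd.DataFrame:
    """Square matrix of observed beta-MNTD values over all site pairs."""
    order = coph.index.tolist()
    counts = community.data.loc[:, order].to_numpy(dtype=float)
    D = coph.to_numpy(dtype=float)
    n = counts.shape[0]
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = beta_mntd(counts[i], counts[j], D)
    return pd.DataFrame(out, index=community.site_ids, columns=community.site_ids)


def pairwise_bray_curtis(community: CommunityMatrix) -> pd.DataFrame:
    """Square matrix of Bray-Curtis dissimilarities over all site pairs."""
    counts = community.counts
    n = counts.shape[0]
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(counts[i], counts[j])
    return pd.DataFrame(out, index=community.site_ids, columns=community.site_ids)
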