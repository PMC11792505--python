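"""Phylogenetic-signal gate: Mantel correlogram of niche differences
against phylogenetic distance.

Turnover-based inference assumes that ecological niches are conserved on
the phylogeny, at least among close relatives.  The standard check is a
Mantel correlogram: between-taxon niche differences are correlated with
membership in successive phylogenetic distance classes; a significantly
positive correlation in the shortest class(es) indicates that close
relatives have similar niches.  The construction follows the widely used
vegan ``mantel.correlog`` conventions: Sturges' rule for the number of
equal-width distance classes, the correlation sign flipped so positive r
means within-class similarity, one-tailed permutation tests in the
direction of the observed sign, and progressive Holm correction.

The gate is advisory: downstream analysis proceeds with a warning if no
class is significant.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .io import CommunityMatrix, Phylogeny

__all__ = ["taxon_niche", "mantel_correlogram", "phylogenetic_signal"]

_TAG_MANTEL = 47


def taxon_niche(community: CommunityMatrix, covariate: pd.Series) -> pd.Series:
    """Abundance-weighted mean environment of each taxon.

    niche_i = sum_k (x_ik / sum_k x_ik) * env_k, in the covariate's units;
    it is bounded by the covariate's observed range.
    """
    covariate = covariate.reindex(community.site_ids)
    if covariate.isna().any():
        missing = covariate.index[covariate.isna()].tolist()
        raise ValueError(f"covariate missing for sites: {missing}")
    counts = community.data
    weights = counts.div(counts.sum(axis=0), axis=1)
    return weights.mul(covariate, axis=0).sum(axis=0)


def _holm_progressive(p: np.ndarray) -> np.ndarray:
    """vegan-style progressive Holm: entry i is holm(p[: i + 1])[i]."""
    out = np.full_like(p, np.nan, dtype=float)
    for i in range(len(p)):
        sub = p[: i + 1]
        order = np.argsort(sub, kind="stable")
        adj = np.empty(i + 1)
        running = 0.0
        for rank, pos in enumerate(order):
            running = max(running, min(1.0, sub[pos] * (i + 1 - rank)))
            adj[pos] = running
        out[i] = adj[i]
    return out


def mantel_correlogram(
    niche: pd.Series,
    coph: pd.DataFrame,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
    cutoff: bool = True,
    alpha: float = 0.05,
    tail: str = "auto",
) -> pd.DataFrame:
    """Mantel correlogram of |niche difference| against phylogenetic distance.

    Parameters
    ----------
    niche :
        Per-taxon niche values; must cover every taxon of ``coph``.
    coph :
        Patristic distance matrix (taxa x taxa).
    n_classes :
        Number of equal-width distance classes; default Sturges' rule,
        ceil(1 + log2(#pairs)).
    n_perm :
        Taxon-label permutations for the per-class test (>= 99).
    cutoff :
        Drop classes beyond the halfway point in which some taxon has no
        pair (the vegan convention); their rows carry NaN statistics.
    tail :
        ``"auto"`` (one-tailed in the direction of the observed sign, the
        vegan convention), ``"positive"`` (upper tail) or ``"two-sided"``.

    Returns
    -------
    DataFrame with one row per distance class: bounds and center, number
    of taxon pairs, Mantel r (positive = within-class similarity),
    permutation p, progressively Holm-corrected p, and a significance
    flag at ``alpha``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if tail not in ("auto", "positive", "two-sided"):
        raise ValueError("tail must be 'auto', 'positive' or 'two-sided'")
    taxa = coph.index.tolist()
    vals = niche.reindex(taxa)
    if vals.isna().any():
        missing = vals.index[vals.isna()].tolist()
        raise ValueError(f"niche undefined for taxa: {missing}")
    x = vals.to_numpy(dtype=float)
    D = coph.to_numpy(dtype=float)
    n = len(taxa)
    iu, ju = np.triu_indices(n, k=1)
    dphy = D[iu, ju]
    n_pairs = dphy.size
    if n_classes is None:
        n_classes = math.ceil(1 + math.log2(n_pairs))
    breaks = np.linspace(dphy.min(), dphy.max(), n_classes + 1)
    breaks[0] -= 1e-9 * max(1.0, abs(breaks[0]))
    cls = np.searchsorted(breaks, dphy, side="left") - 1  # 0-based class ids

    dniche = np.abs(x[iu] - x[ju])
    rng = np.random.default_rng([int(seed), _TAG_MANTEL])
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    xp = x[perms]  # (P, n)
    dn_perm = np.abs(xp[:, iu] - xp[:, ju])  # (P, n_pairs)

    half = n_classes // 2
    rows = []
    for c in range(n_classes):
        member = cls == c
        n_in = int(member.sum())
        row = {
            "class_index": c + 1,
            "d_lower": breaks[c],
            "d_upper": breaks[c + 1],
            "d_center": 0.5 * (breaks[c] + breaks[c + 1]),
            "n_pairs": n_in,
            "r": np.nan,
            "p": np.nan,
        }
        if n_in < 2 or n_in == n_pairs:
            warnings.warn(
                f"distance class {c + 1} dropped ({n_in} pairs)",
                UserWarning,
                stacklevel=2,
            )
            rows.append(row)
            continue
        if cutoff and c + 1 > half:
            # some taxon has no pair in this class: stop, as vegan does
            in_class = np.zeros((n, n), dtype=bool)
            in_class[iu[member], ju[member]] = True
            covered = in_class.any(axis=0) | in_class.any(axis=1)
            if not covered.all():
                rows.append(row)
                continue
        y = member.astype(float)
        yc = y - y.mean()
        ynorm = float(np.sqrt((yc**2).sum()))
        dn_c = dniche - dniche.mean()
        dnorm = float(np.sqrt((dn_c**2).sum()))
        if dnorm == 0.0:
            row["r"], row["p"] = 0.0, np.nan  # zero-variance niche distances
            rows.append(row)
            continue
        r_obs = -float(dn_c @ yc) / (dnorm * ynorm)
        pc = dn_perm - dn_perm.mean(axis=1, keepdims=True)
        pnorm = np.sqrt((pc**2).sum(axis=1))
        r_perm = -(pc @ yc) / (pnorm * ynorm)
        # 1e-12 slack keeps tail counts (hence p) exactly invariant under
        # affine rescaling of the niche values
        if tail == "positive" or (tail == "auto" and r_obs >= 0):
            p_val = (np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1)
        elif tail == "auto":
            p_val = (np.sum(r_perm <= r_obs + 1e-12) + 1) / (n_perm + 1)
        else:
            p_val = (np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12) + 1) / (n_perm + 1)
        row["r"], row["p"] = r_obs, float(p_val)
        rows.append(row)
    out = pd.DataFrame(rows)
    valid = out["p"].notna().to_numpy()
    p_corr = np.full(len(out), np.nan)
    if valid.any():
        p_corr[valid] = _holm_progressive(out.loc[valid, "p"].to_numpy())
    out["p_corrected"] = p_corr
    out["significant"] = out["p_corrected"] <= alpha
    return out


def phylogenetic_signal(
    community: CommunityMatrix,
    tree: Phylogeny,
    covariate: pd.Series,
    **kwargs,
) -> pd.DataFrame:
    """Convenience gate: niche estimate + Mantel correlogram.

    Warns (but does not block) when no distance class shows significant
    signal.
    """
    niche = taxon_niche(community, covariate)
    coph = tree.cophenetic(order=sorted(t for t in tree.tip_labels if t in niche.index))
    result = mantel_correlogram(niche, coph, **kwargs)
    if not result["significant"].any():
        warnings.warn(
            "no phylogenetic signal detected in any distance class; "
            "turnover-based process inference may be unreliable",
            UserWarning,
            stacklevel=2,
        )
    return result
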