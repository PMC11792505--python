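"""Sampling-unit (DSU) attribution by pair counting.

A sampling unit's (or group of units') contribution to each assembly
process is the fraction of classified site pairs *involving* it -- pairs
with at least one endpoint in the target set -- that carry each process
label.  With n sites there are n(n-1)/2 pairs overall; a single site is
involved in n-1 of them, a group of g sites in C(n,2) - C(n-g,2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nulls import PROCESSES

__all__ = ["DsuTarget", "pairs_involving", "attribute_sites", "group_summary"]

STOCHASTIC = ("dispersal_limitation", "homogenizing_dispersal", "drift")


@dataclass(frozen=True)
class DsuTarget:
    """A named, non-empty set of sampling units."""

    target_id: str
    member_sites: tuple[str, ...]

    def __post_init__(self):
        if not self.member_sites:
            raise ValueError(f"DSU target {self.target_id!r} has no member sites")


def pairs_involving(
    target: DsuTarget,
    all_sites: list[str],
    between_only: bool = False,
) -> list[tuple[str, str]]:
    """All unordered site pairs with at least one endpoint in ``target``.

    Pairs are returned in lexicographic order, each pair sorted
    internally.  ``between_only=True`` drops pairs whose two endpoints are
    both target members.
    """
    members = set(target.member_sites)
    missing = members - set(all_sites)
    if missing:
        raise KeyError(
            f"DSU target {target.target_id!r} has unknown sites: {sorted(missing)}"
        )
    sites = sorted(set(all_sites))
    pairs = []
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            n_in = (a in members) + (b in members)
            if n_in == 0:
                continue
            if between_only and n_in == 2:
                continue
            pairs.append((a, b))
    return pairs


def attribute_sites(
    pair_metrics: pd.DataFrame,
    targets: list[DsuTarget],
    between_only: bool = False,
) -> pd.DataFrame:
    """Per-target process profile over involved pairs.

    For each target: the number of involved pairs, the number of
    evaluable (non-degenerate) ones among them, the per-process fractions
    over evaluable pairs (summing to one), the headline significant
    fraction (pairs with a significant SES or RC, i.e. any label other
    than drift), and the stochasticity (dispersal + drift fraction).
    Targets with no evaluable involved pair are flagged with NaN
    fractions.
    """
    all_sites = sorted(set(pair_metrics["site_a"]) | set(pair_metrics["site_b"]))
    key = {
        tuple(sorted((a, b))): (proc, status)
        for a, b, proc, status in zip(
            pair_metrics["site_a"],
            pair_metrics["site_b"],
            pair_metrics["process"],
            pair_metrics["status"],
        )
    }
    records = []
    for target in targets:
        involved = pairs_involving(target, all_sites, between_only=between_only)
        labels = [key[p][0] for p in involved if p in key and key[p][1] == "ok"]
        rec = {
            "target_id": target.target_id,
            "n_sites": len(target.member_sites),
            "n_involved": len(involved),
            "n_evaluable": len(labels),
        }
        if labels:
            counts = pd.Series(labels).value_counts()
            for proc in PROCESSES:
                rec[proc] = float(counts.get(proc, 0)) / len(labels)
            rec["significant_fraction"] = float(
                sum(1 for x in labels if x != "drift")
            ) / len(labels)
            rec["stochasticity"] = float(sum(rec[p] for p in STOCHASTIC))
        else:
            for proc in PROCESSES:
                rec[proc] = np.nan
            rec["significant_fraction"] = np.nan
            rec["stochasticity"] = np.nan
        records.append(rec)
    cols = [
        "target_id",
        "n_sites",
        "n_involved",
        "n_evaluable",
        *PROCESSES,
        "significant_fraction",
        "stochasticity",
    ]
    return pd.DataFrame(records, columns=cols)


def group_summary(
    pair_metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str,
    between_only: bool = False,
) -> pd.DataFrame:
    """DSU attribution with one target per metadata group.

    Every site appearing in ``pair_metrics`` must carry a group label in
    ``metadata[group_col]``; an unmapped site raises an error naming it.
    """
    if group_col not in metadata.columns:
        raise KeyError(f"group column {group_col!r} not in metadata")
    all_sites = sorted(set(pair_metrics["site_a"]) | set(pair_metrics["site_b"]))
    labels = metadata[group_col]
    unmapped = [s for s in all_sites if s not in labels.index or pd.isna(labels.get(s))]
    if unmapped:
        raise ValueError(f"sites without a {group_col!r} group label: {unmapped}")
    targets = [
        DsuTarget(str(g), tuple(s for s in all_sites if labels[s] == g))
        for g in sorted(labels.loc[all_sites].unique(), key=str)
    ]
    return attribute_sites(pair_metrics, targets, between_only=between_only)
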