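"""The fitted-model interface: :class:`AssemblyModel` and
:class:`AssemblyResults`.

An :class:`AssemblyModel` binds an aligned community table and phylogeny
(plus optional taxonomy and sample metadata).  ``fit()`` runs the two-step
null-model analysis for every site pair -- SES.beta-MNTD from tip-label
shuffling, then Raup-Crick Bray-Curtis for pairs without a selection
signal -- and returns an :class:`AssemblyResults` carrying the per-pair
metrics and process labels.  Taxon-removal attribution and sampling-unit
attribution hang off the results object and replay the fit's
randomizations.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .io import CommunityMatrix, Phylogeny, align, read_community_table, read_tree
from .nulls import (
    DEGENERATE_SD,
    PROCESSES,
    NullConfig,
    _pair_rng,
    classify_pair,
    rc_bray,
    ses_beta_mntd,
    tip_permutations,
)

__all__ = ["AssemblyModel", "AssemblyResults", "PAIR_COLUMNS"]

#: Column order of the per-pair metrics table (stable for TSV output).
PAIR_COLUMNS = [
    "site_a",
    "site_b",
    "beta_mntd",
    "null_mean",
    "null_sd",
    "ses",
    "rc",
    "process",
    "status",
]


class AssemblyModel:
    """Two-step community assembly analysis for one dataset.

    Parameters
    ----------
    community :
        Sites x taxa abundance table (at least two sites).
    tree :
        Rooted phylogeny covering the table's taxa.  Taxa missing from the
        tree are dropped from the table with a warning.
    taxonomy :
        Optional taxon -> rank-label table, enabling group-level taxon
        attribution (``rank="phylum"`` etc.).
    metadata :
        Optional site metadata, enabling grouped sampling-unit attribution
        and the environmental niche estimate for the phylogenetic-signal
        gate.
    prune_tree :
        Prune tree tips absent from the table (default).  Keeping them
        enlarges the tip-shuffle pool; a removal analysis re-run from
        scratch on a taxon-filtered table needs ``prune_tree=False`` with
        the original tree to reproduce the pooled randomizations.
    ses_cut, rc_cut, rule_labels :
        See :class:`ecoassembly.nulls.NullConfig`.
    """

    def __init__(
        self,
        community: CommunityMatrix,
        tree: Phylogeny,
        taxonomy: pd.DataFrame | None = None,
        metadata: pd.DataFrame | None = None,
        *,
        prune_tree: bool = True,
        ses_cut: float = 2.0,
        rc_cut: float = 0.95,
        rule_labels: str = "consistent",
    ):
        community, tree = align(community, tree, prune_tree=prune_tree)
        if community.n_sites < 2:
            raise ValueError("pairwise analysis needs at least two sites")
        self.community = community
        self.tree = tree
        self.taxonomy = taxonomy
        self.metadata = metadata
        self.ses_cut = float(ses_cut)
        self.rc_cut = float(rc_cut)
        self.rule_labels = rule_labels

        # The randomization pool is every tip of the aligned tree, held in
        # sorted label order so results do not depend on input column order.
        self.pool: list[str] = sorted(tree.tip_labels)
        self.pool_index = {t: i for i, t in enumerate(self.pool)}
        self._coph = tree.cophenetic(order=self.pool)
        self.D: np.ndarray = self._coph.to_numpy(dtype=float)

        n_sites, n_pool = community.n_sites, len(self.pool)
        self.counts = np.zeros((n_sites, n_pool), dtype=float)
        cols = [self.pool_index[t] for t in community.taxon_ids]
        self.counts[:, cols] = community.counts
        self.occupancy = (self.counts > 0).sum(axis=0).astype(float)
        self.pool_counts = self.counts.sum(axis=0)
        self.site_ids = community.site_ids

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_files(
        cls,
        table_path,
        tree_path,
        taxonomy_path=None,
        metadata_path=None,
        orientation: str = "taxa-by-samples",
        **kwargs,
    ) -> "AssemblyModel":
        from .io import read_metadata, read_taxonomy

        community = read_community_table(table_path, orientation=orientation)
        tree = read_tree(tree_path)
        taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
        metadata = read_metadata(metadata_path) if metadata_path else None
        return cls(community, tree, taxonomy=taxonomy, metadata=metadata, **kwargs)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, tree: Phylogeny, **kwargs) -> "AssemblyModel":
        """Build from a sites x taxa DataFrame and a :class:`Phylogeny`."""
        return cls(CommunityMatrix(data), tree, **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self, n_reps: int = 500, seed: int = 0) -> "AssemblyResults":
        """Run the two-step analysis over all site pairs.

        SES.beta-MNTD is computed for every pair from ``n_reps`` shared
        tip-label permutations; Raup-Crick Bray-Curtis is computed only
        for pairs whose |SES| does not exceed ``ses_cut``.  Identical
        seeds give identical results, bit for bit.
        """
        cfg = NullConfig(
            n_reps=n_reps,
            seed=seed,
            ses_cut=self.ses_cut,
            rc_cut=self.rc_cut,
            rule_labels=self.rule_labels,
        )
        counts = self.counts
        if not np.allclose(counts, np.round(counts), atol=1e-9):
            warnings.warn(
                "abundances are not integers; the Raup-Crick null rounds "
                "site totals and treats values > 0 as presences",
                UserWarning,
                stacklevel=2,
            )
        perms = tip_permutations(len(self.pool), cfg.n_reps, cfg.seed)
        rows = []
        pairs = list(itertools.combinations(range(len(self.site_ids)), 2))
        for i, j in pairs:
            obs, mean, sd, ses = ses_beta_mntd(self.D, perms, counts[i], counts[j])
            rc = float("nan")
            if sd <= DEGENERATE_SD:
                status, process = "degenerate", "unclassifiable"
            else:
                status = "ok"
                if abs(ses) <= cfg.ses_cut:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        rc = rc_bray(
                            np.round(counts[i]),
                            np.round(counts[j]),
                            self.occupancy,
                            self.pool_counts,
                            cfg.n_reps,
                            _pair_rng(cfg.seed, i, j),
                        )
                process = classify_pair(ses, rc if not np.isnan(rc) else None, cfg)
            rows.append(
                {
                    "site_a": self.site_ids[i],
                    "site_b": self.site_ids[j],
                    "beta_mntd": obs,
                    "null_mean": mean,
                    "null_sd": sd,
                    "ses": ses,
                    "rc": rc,
                    "process": process,
                    "status": status,
                }
            )
        table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
        return AssemblyResults(self, cfg, perms, table)


class AssemblyResults:
    """Results of :meth:`AssemblyModel.fit`.

    Attributes
    ----------
    pair_metrics :
        One row per site pair: observed beta-MNTD, null mean/sd, SES, RC
        (NaN where not required), the assigned process and a status flag
        (``ok`` or ``degenerate``).
    """

    def __init__(
        self,
        model: AssemblyModel,
        cfg: NullConfig,
        perms: np.ndarray,
        pair_metrics: pd.DataFrame,
    ):
        self.model = model
        self.cfg = cfg
        self.perms = perms
        self.pair_metrics = pair_metrics

    # -- headline numbers ------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.pair_metrics)

    @property
    def process_counts(self) -> pd.Series:
        ok = self.pair_metrics[self.pair_metrics["status"] == "ok"]
        return ok["process"].value_counts().reindex(PROCESSES, fill_value=0)

    @property
    def process_fractions(self) -> pd.Series:
        counts = self.process_counts
        total = counts.sum()
        return counts / total if total else counts.astype(float)

    @property
    def stochasticity(self) -> float:
        """Fraction of classified pairs assigned to a stochastic process."""
        f = self.process_fractions
        return float(
            f[["dispersal_limitation", "homogenizing_dispersal", "drift"]].sum()
        )

    # -- attribution -----------------------------------------------------
    def attribute_taxa(self, targets=None, rank: str | None = None, progress: bool = False):
        """Removal-based taxon (DTU) attribution; see :func:`ecoassembly.removal.attribute_taxa`."""
        from .removal import attribute_taxa, targets_from_taxonomy

        if targets is None:
            if rank is not None:
                if self.model.taxonomy is None:
                    raise ValueError("rank-level attribution needs a taxonomy map")
                targets = targets_from_taxonomy(
                    self.model.taxonomy, rank, self.model.community.taxon_ids
                )
            else:
                from .removal import RemovalTarget

                targets = [
                    RemovalTarget(t, (t,)) for t in self.model.community.taxon_ids
                ]
        return attribute_taxa(self, targets, progress=progress)

    def attribute_sites(self, targets=None, group_col: str | None = None, between_only: bool = False):
        """Pair-counting sampling-unit (DSU) attribution; see :mod:`ecoassembly.sampling_units`."""
        from .sampling_units import DsuTarget, attribute_sites, group_summary

        if group_col is not None:
            if self.model.metadata is None:
                raise ValueError("grouped attribution needs sample metadata")
            return group_summary(
                self.pair_metrics, self.model.metadata, group_col, between_only=between_only
            )
        if targets is None:
            targets = [DsuTarget(s, (s,)) for s in self.model.site_ids]
        return attribute_sites(self.pair_metrics, targets, between_only=between_only)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted classification."""
        lines = [
            "Community assembly process classification",
            "=" * 48,
            f"sites: {len(self.model.site_ids)}    taxa (pool): {len(self.model.pool)}",
            f"site pairs: {self.n_pairs}    randomizations: {self.cfg.n_reps}"
            f"    seed: {self.cfg.seed}",
            f"thresholds: |SES| > {self.cfg.ses_cut:g}, |RC| > {self.cfg.rc_cut:g}",
            "-" * 48,
        ]
        counts, fracs = self.process_counts, self.process_fractions
        for proc in PROCESSES:
            lines.append(f"{proc:<26s} {counts[proc]:>5d}  ({fracs[proc]:6.1%})")
        n_deg = int((self.pair_metrics["status"] != "ok").sum())
        lines.append("-" * 48)
        lines.append(f"degenerate / unclassifiable pairs: {n_deg}")
        lines.append(f"stochasticity (dispersal + drift): {self.stochasticity:.1%}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.pair_metrics.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot_process_fractions(self, ax=None):  # pragma: no cover - optional plotting
        """Minimal stacked-bar rendering of the process fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        bottom = 0.0
        for proc in PROCESSES:
            frac = float(self.process_fractions[proc])
            ax.bar(["all pairs"], [frac], bottom=bottom, label=proc)
            bottom += frac
        ax.set_ylabel("fraction of classified pairs")
        ax.legend(fontsize=7)
        return ax

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<AssemblyResults: {self.n_pairs} pairs, "
            f"{self.cfg.n_reps} reps, seed={self.cfg.seed}>"
        )
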