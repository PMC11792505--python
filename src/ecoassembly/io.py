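"""Reading, validation and alignment of community tables, trees and metadata.

The pipeline operates on two core containers:

* :class:`CommunityMatrix` -- a sites x taxa table of non-negative
  abundances (counts or relative abundances).
* :class:`Phylogeny` -- a rooted tree with branch lengths whose tip set
  covers the table's taxa after :func:`align`.

Tables are tab-separated text (``#`` comment lines ignored).  The default
orientation is taxa-as-rows / samples-as-columns, the common export
convention of amplicon pipelines; pass ``orientation="samples-by-taxa"``
to transpose.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "Phylogeny",
    "read_community_table",
    "read_tree",
    "read_taxonomy",
    "read_metadata",
    "align",
]

#: Sentinel used for missing taxonomy ranks.
UNCLASSIFIED = "Unclassified"

_RANK_ORDER = ["kingdom", "domain", "phylum", "class", "order", "family", "genus", "species"]
_RANK_PREFIXES = {
    "k__": "kingdom",
    "d__": "domain",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}


class CommunityMatrix:
    """Sites x taxa abundance table.

    Parameters
    ----------
    data :
        DataFrame with site identifiers as the index and taxon identifiers
        as columns.  Values must be non-negative and finite.
    drop_empty_taxa :
        Drop taxa with zero total abundance (with a warning).  Taxa absent
        from every site carry no information for pairwise turnover.
    """

    def __init__(self, data: pd.DataFrame, drop_empty_taxa: bool = True):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        try:
            values = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"community table contains non-numeric entries: {exc}") from exc
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("community table contains NaN or infinite entries")
        neg = values.lt(0)
        if neg.to_numpy().any():
            site = neg.any(axis=1).idxmax()
            taxon = neg.loc[site].idxmax()
            raise ValueError(
                f"negative abundance at site {site!r}, taxon {taxon!r}: "
                f"{values.at[site, taxon]}"
            )
        empty_sites = values.sum(axis=1) <= 0
        if empty_sites.any():
            names = values.index[empty_sites].tolist()
            raise ValueError(f"sites with zero total abundance: {names}")
        if drop_empty_taxa:
            empty = values.sum(axis=0) <= 0
            if empty.any():
                dropped = values.columns[empty].tolist()
                warnings.warn(
                    f"dropping {len(dropped)} all-zero taxa: {dropped[:10]}"
                    + ("..." if len(dropped) > 10 else ""),
                    UserWarning,
                    stacklevel=2,
                )
                values = values.loc[:, ~empty]
        self.data: pd.DataFrame = values
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None

    # -- basic accessors -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def counts(self) -> np.ndarray:
        """Abundances as a float array, sites x taxa."""
        return self.data.to_numpy(dtype=float)

    @property
    def is_integer(self) -> bool:
        vals = self.counts
        return bool(np.allclose(vals, np.round(vals), atol=1e-9))

    # -- transforms ------------------------------------------------------
    def relative_abundances(self) -> pd.DataFrame:
        """Site-wise relative abundances (each row sums to one)."""
        totals = self.data.sum(axis=1)
        return self.data.div(totals, axis=0)

    def subset_taxa(self, taxa: Sequence[str]) -> "CommunityMatrix":
        """Restrict to ``taxa`` (kept in the given order)."""
        missing = [t for t in taxa if t not in self.data.columns]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        return CommunityMatrix(self.data.loc[:, list(taxa)], drop_empty_taxa=False)

    def drop_taxa(self, taxa: Iterable[str]) -> "CommunityMatrix":
        keep = [t for t in self.taxon_ids if t not in set(taxa)]
        if not keep:
            raise ValueError("dropping these taxa would empty the table")
        return CommunityMatrix(self.data.loc[:, keep], drop_empty_taxa=False)

    def to_tsv(self, path, orientation: str = "taxa-by-samples") -> None:
        _check_orientation(orientation)
        df = self.data.T if orientation == "taxa-by-samples" else self.data
        df.to_csv(path, sep="\t", index_label="id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<CommunityMatrix: {self.n_sites} sites x {self.n_taxa} taxa>"


class Phylogeny:
    """Rooted phylogeny with branch lengths, backed by a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
            if leaf.edge.length is None:
                raise ValueError(f"tip {leaf.taxon.label!r} has no branch length")
            if leaf.edge.length < 0:
                raise ValueError(f"negative branch length at tip {leaf.taxon.label!r}")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # root edge may legitimately lack a length
            if node.edge.length is None:
                raise ValueError("an internal branch has no length")
            if node.edge.length < 0:
                raise ValueError("an internal branch has negative length")
        self.tree = tree
        self._tip_labels = labels

    @classmethod
    def read(cls, path) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"failed to parse newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"failed to parse newick: {exc}") from exc
        return cls(tree)

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def prune_to(self, labels: Sequence[str]) -> "Phylogeny":
        """Return a copy restricted to ``labels`` (patristic distances kept)."""
        keep = set(labels)
        missing = keep - set(self._tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if keep == set(self._tip_labels):
            return self
        pruned = self.tree.extract_tree_with_taxa_labels(labels=list(keep))
        return Phylogeny(pruned)

    def cophenetic(self, order: Sequence[str] | None = None) -> pd.DataFrame:
        """Patristic (tip-to-tip path) distance matrix.

        Parameters
        ----------
        order :
            Tip label order for the rows/columns; defaults to sorted labels.
        """
        if order is None:
            order = sorted(self._tip_labels)
        taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in set(order)}
        missing = [lab for lab in order if lab not in taxa]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        pdm = self.tree.phylogenetic_distance_matrix()
        n = len(order)
        D = np.zeros((n, n), dtype=float)
        for i in range(n):
            ti = taxa[order[i]]
            for j in range(i + 1, n):
                d = pdm.patristic_distance(ti, taxa[order[j]])
                D[i, j] = D[j, i] = d
        return pd.DataFrame(D, index=list(order), columns=list(order))

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny: {self.n_tips} tips>"


def _check_orientation(orientation: str) -> None:
    if orientation not in ("taxa-by-samples", "samples-by-taxa"):
        raise ValueError(
            "orientation must be 'taxa-by-samples' or 'samples-by-taxa', "
            f"got {orientation!r}"
        )


def read_community_table(path, orientation: str = "taxa-by-samples") -> CommunityMatrix:
    """Read a TSV abundance table into a :class:`CommunityMatrix`.

    All-zero taxa are dropped with a warning; negative entries, duplicate
    identifiers and empty sites are rejected.
    """
    _check_orientation(orientation)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if orientation == "taxa-by-samples":
        df = df.T
    return CommunityMatrix(df)


def read_tree(path) -> Phylogeny:
    """Read a rooted newick tree; every tip must be labeled with a length."""
    return Phylogeny.read(path)


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy map (taxon id -> rank labels).

    Accepts either one column per rank (``phylum``, ``class``, ...) or a
    single lineage-string column in the ``k__...; p__...`` convention,
    which is split into rank columns.  Missing ranks become
    ``"Unclassified"``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon identifiers in taxonomy: {dups}")
    cols = {c.lower(): c for c in df.columns}
    lineage_col = next(
        (cols[c] for c in ("taxon", "taxonomy", "lineage") if c in cols), None
    )
    if lineage_col is not None and not any(r in cols for r in _RANK_ORDER):
        parsed = df[lineage_col].apply(_split_lineage)
        out = pd.DataFrame(list(parsed), index=df.index)
    else:
        out = df.rename(columns={cols[c]: c for c in _RANK_ORDER if c in cols})
        out = out.loc[:, [c for c in _RANK_ORDER if c in out.columns]]
    out = out.reindex(columns=[c for c in _RANK_ORDER if c in out.columns])
    out = out.fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
    return out


def _split_lineage(lineage: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if not isinstance(lineage, str):
        return out
    for part in lineage.split(";"):
        part = part.strip()
        prefix = part[:3]
        if prefix in _RANK_PREFIXES:
            out[_RANK_PREFIXES[prefix]] = part[3:].strip() or UNCLASSIFIED
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata table (site id in the first column)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate site identifiers in metadata: {dups}")
    return df


def align(
    community: CommunityMatrix,
    tree: Phylogeny,
    prune_tree: bool = True,
) -> tuple[CommunityMatrix, Phylogeny]:
    """Reconcile a community table with a phylogeny.

    Taxa absent from the tree are dropped from the table (reported via a
    warning); tips absent from the table are pruned unless
    ``prune_tree=False`` (keeping them enlarges the randomization pool,
    which is what a from-scratch re-run on a taxon-filtered table needs in
    order to reproduce a removal analysis exactly).

    The operation is idempotent.
    """
    table_taxa = set(community.taxon_ids)
    tips = set(tree.tip_labels)
    shared = table_taxa & tips
    if not shared:
        raise ValueError("community table and tree share no taxa")
    lost = [t for t in community.taxon_ids if t not in tips]
    if lost:
        warnings.warn(
            f"dropping {len(lost)} table taxa absent from the tree: {lost[:10]}"
            + ("..." if len(lost) > 10 else ""),
            UserWarning,
            stacklevel=2,
        )
        community = community.subset_taxa([t for t in community.taxon_ids if t in tips])
    if prune_tree and tips - shared:
        tree = tree.prune_to(sorted(shared))
    return community, tree
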