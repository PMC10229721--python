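"""Phylogenetic trees and patristic distance matrices.

Trees are read from Newick with branch lengths in millions of years (Myr).
The only tree manipulations supported are pruning to a species set and
random within-genus substitution for records identified to genus level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import (
    GenusResolutionError,
    MissingSpeciesError,
    NewickParseError,
    TreeValidationError,
)

__all__ = ["PhyloTree", "DistanceMatrix", "parse_newick", "patristic_matrix", "substitute_genus"]


@dataclass
class PhyloTree:
    """A rooted tree with unique tip labels and non-negative branch lengths (Myr)."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {leaf.taxon.label: leaf.root_distance for leaf in self.tree.leaf_node_iter()}

    def validate(self) -> None:
        labels = self.tip_labels
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise TreeValidationError(
                    f"missing branch length above node {edge.head_node}"
                )
            if not np.isfinite(edge.length) or edge.length < 0:
                raise TreeValidationError(f"invalid branch length {edge.length}")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Raises :class:`NewickParseError` on malformed input (the message names
    the offending position where the underlying parser reports one) and
    :class:`TreeValidationError` on duplicate tip labels or bad branch
    lengths.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Multiple occurrences of the same taxa" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    pt = PhyloTree(tree)
    pt.validate()
    return pt


@dataclass
class DistanceMatrix:
    """Square symmetric patristic distance matrix (Myr) with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < 0).any():
            raise ValueError("negative distances")
        self._index = {l: i for i, l in enumerate(self.labels)}

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self._index[a], self._index[b]]

    def submatrix(self, species) -> "DistanceMatrix":
        missing = [s for s in species if s not in self._index]
        if missing:
            raise MissingSpeciesError(missing)
        idx = [self._index[s] for s in species]
        return DistanceMatrix(tuple(species), self.values[np.ix_(idx, idx)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


def patristic_matrix(tree: PhyloTree, species=None) -> DistanceMatrix:
    """Pairwise path-length distances between tips, in Myr.

    ``species`` restricts (and orders) the output; defaults to all tips in
    tree order. Unknown species raise :class:`MissingSpeciesError` listing
    every missing name.
    """
    tips = tree.tip_labels
    if species is None:
        species = tips
    species = list(species)
    tipset = set(tips)
    missing = [s for s in species if s not in tipset]
    if missing:
        raise MissingSpeciesError(missing)

    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace if t.label in tipset}
    n = len(species)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
            out[i, j] = out[j, i] = d
    if n > 1 and (out[~np.eye(n, dtype=bool)] == 0).any():
        warnings.warn(
            "zero patristic distance between distinct tips (zero-length branches)",
            UserWarning,
            stacklevel=2,
        )
    return DistanceMatrix(tuple(species), out)


def genus_of(name: str) -> str:
    """First whitespace-delimited token of a binomial."""
    return name.split()[0] if name.split() else name


def substitute_genus(taxon: str, tree: PhyloTree, seed: int) -> str:
    """Pick a random congeneric tip for a genus-level record.

    Deterministic for a given seed. Raises :class:`GenusResolutionError`
    when the tree holds no tip of that genus.
    """
    genus = genus_of(taxon)
    congeners = sorted(t for t in tree.tip_labels if genus_of(t) == genus)
    if not congeners:
        raise GenusResolutionError(f"no tip of genus '{genus}' in tree")
    rng = np.random.default_rng(seed)
    return congeners[rng.integers(len(congeners))]
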