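"""Gene origination dating from ortholog presence/absence on a species tree.

The model is Dollo parsimony: a gene arises once on the lineage leading to
the focal species and can be lost but never regained.  On a rooted tree the
root-to-focal-tip path visits internal nodes ``v0 .. v(B-1)``; each ``vi``
splits off an outgroup clade ``O_i`` (the tips on the non-focal side).
Branch ``i`` is the path segment ending at ``vi``; branch ``B`` is the focal
terminal branch.  A gene present in some tip of an old outgroup clade must
predate that split, so the assigned origination branch is the *smallest*
``i`` with presence in ``O_i`` — the oldest age compatible with the data.
Losses can therefore only make a gene look younger, never older.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

YOUNG = "young"
OLD = "old"


class DatingError(ValueError):
    pass


@dataclass(frozen=True)
class FocalPath:
    """A rooted species tree resolved into the focal lineage's outgroup clades.

    Attributes
    ----------
    focal : name of the focal tip (the species whose genes are dated).
    outgroups : ``outgroups[i]`` is the tip set of clade ``O_i`` diverging at
        the i-th node on the root-to-focal path; branch indices run 0
        (oldest) through ``n_branches`` (the focal terminal branch).
    """

    focal: str
    outgroups: tuple[frozenset[str], ...]
    tips: frozenset[str] = field(default=frozenset())

    @property
    def n_branches(self) -> int:
        """Index of the terminal (focal-specific) branch."""
        return len(self.outgroups)

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, focal: str) -> "FocalPath":
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        if focal not in leaves:
            raise DatingError(f"focal tip {focal!r} not found in tree")
        if tree.seed_node is None or len(tree.seed_node.child_nodes()) < 2:
            raise DatingError("tree must be rooted with a bifurcating root")
        # walk root -> focal, collecting the off-path clade at each node
        path = []
        node = leaves[focal]
        while node.parent_node is not None:
            path.append(node.parent_node)
            node = node.parent_node
        path.reverse()  # root first
        outgroups = []
        for i, vi in enumerate(path):
            children = vi.child_nodes()
            if len(children) != 2:
                raise DatingError(
                    f"multifurcation at node {i} on the focal path; resolve the tree first"
                )
            on_path = path[i + 1] if i + 1 < len(path) else leaves[focal]
            off = [c for c in children if c is not on_path]
            clade = frozenset(
                lf.taxon.label for lf in off[0].leaf_iter()
            )
            outgroups.append(clade)
        return cls(
            focal=focal,
            outgroups=tuple(outgroups),
            tips=frozenset(leaves),
        )

    @classmethod
    def from_newick(cls, newick: str, focal: str) -> "FocalPath":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_tree(tree, focal)

    @classmethod
    def from_file(cls, path, focal: str) -> "FocalPath":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls.from_tree(tree, focal)


def assign_origination_branch(tree: FocalPath, present: Iterable[str]) -> int:
    """Origination branch of one gene: oldest outgroup presence wins.

    ``present`` is the set of species carrying an ortholog; it must include
    the focal species.  Returns ``min{i : O_i ∩ present ≠ ∅}``, or the
    terminal branch index when no outgroup carries the gene.
    """
    pres = set(present)
    unknown = pres - tree.tips
    if unknown:
        raise DatingError(f"species not in tree: {sorted(unknown)}")
    if tree.focal not in pres:
        raise DatingError(f"gene absent in focal species {tree.focal!r}")
    for i, clade in enumerate(tree.outgroups):
        if pres & clade:
            return i
    return tree.n_branches


def date_catalog(tree: FocalPath, presence: pd.DataFrame) -> pd.Series:
    """Date every gene of a presence matrix (genes x species, boolean)."""
    missing = set(presence.columns) - tree.tips
    if missing:
        raise DatingError(f"presence matrix species not in tree: {sorted(missing)}")
    branches = {}
    for gene, row in presence.iterrows():
        branches[gene] = assign_origination_branch(tree, row.index[row.astype(bool)])
    return pd.Series(branches, name="branch")


def classify_age(branch: int, young_branches: Sequence[int]) -> str:
    """Age class: ``young`` iff the origination branch is in the young set.

    For the human tree with branches 0..12 the young set is {8..12}
    (primate-specific), branch 12 being human-specific.
    """
    if len(young_branches) == 0:
        raise DatingError("young branch set is empty")
    return YOUNG if branch in set(young_branches) else OLD


def extract_ancestral_subset(
    one2one: pd.DataFrame,
    homolog: pd.DataFrame,
    ingroup: Sequence[str],
    outgroups: Sequence[str],
) -> set[str]:
    """Stringent ancestral gene set from homology flags.

    Keeps genes with a one-to-one ortholog in *every* ingroup species and no
    homolog of any kind in *any* outgroup species.  Used to split the oldest
    age class, e.g. vertebrate-ancestor genes = 1:1 in both zebrafish and
    fugu with no homolog in tunicates, fly, mosquito, worm or yeast.
    """
    for sp in ingroup:
        if sp not in one2one.columns:
            raise DatingError(f"ingroup species {sp!r} missing from one-to-one table")
    for sp in outgroups:
        if sp not in homolog.columns:
            raise DatingError(f"outgroup species {sp!r} missing from homolog table")
    keep = one2one[list(ingroup)].all(axis=1) & ~homolog[list(outgroups)].any(axis=1)
    return set(one2one.index[keep])
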