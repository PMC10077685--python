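"""Minimum intron gain/loss event inference on a phylogeny.

Intron gains are rare horizontal transfers, so each site is modelled under
Dollo parsimony: a single gain on the edge above the most recent common
ancestor of all strains carrying the intron, plus the minimal set of loss
edges covering exactly the strains lacking it.  Losses of *neighboring*
introns of one gene assigned to the same branch are merged into a single
block event when no site that remains present in the branch's ancestral
state lies between them — the signature of a reverse-transcribed,
intron-less mRNA segment recombining back into the genome.  The reported
count is the number of merged events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "LossEvent",
    "load_tree",
    "branch_id",
    "dollo_loss_branches",
    "infer_min_events",
]


@dataclass(frozen=True)
class LossEvent:
    branch: str
    gene: str
    site_ordinals: frozenset[int]
    kind: str  # loss | gain

    def __str__(self) -> str:
        sites = ",".join(str(o) for o in sorted(self.site_ordinals))
        return f"{self.kind}@{self.branch}:{self.gene}[{sites}]"


def load_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Read a rooted tree from a newick string, file path, or pass through."""
    if isinstance(source, dendropy.Tree):
        source.is_rooted = True
        return source
    text = str(source)
    p = Path(text)
    if len(text) < 4000 and "(" not in text and p.exists():
        tree = dendropy.Tree.get(
            path=str(p), schema="newick", preserve_underscores=True
        )
    else:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    tree.is_rooted = True
    return tree


def branch_id(node: dendropy.Node) -> str:
    """Stable identifier of the edge above ``node``: its sorted leaf set."""
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    if len(leaves) == 1:
        return leaves[0]
    return "|".join(leaves)


def _leaf_states(tree: dendropy.Tree, presence: dict[str, bool]) -> None:
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = labels ^ set(presence)
    if missing:
        raise ValueError(f"leaf/strain mismatch: {sorted(missing)}")


def dollo_loss_branches(
    tree: dendropy.Tree, presence: dict[str, bool]
) -> tuple[str | None, set[str]]:
    """Single-gain Dollo reconstruction of one presence/absence character.

    Returns ``(gain_branch, loss_branches)``.  The gain sits on the edge
    above the MRCA of all presence leaves (``"root"`` when that MRCA is the
    root, i.e. the character is ancestrally present).  Losses are the edges
    above each maximal all-absent subtree below the gain node; this is the
    unique minimal loss set under a single gain.  A character absent from
    every leaf yields ``(None, set())``.
    """
    _leaf_states(tree, presence)
    present_leaves = [l for l, p in presence.items() if p]
    if not present_leaves:
        return None, set()
    if len(present_leaves) == len(presence):
        gain_node = tree.seed_node
    else:
        taxa = [
            lf.taxon
            for lf in tree.leaf_node_iter()
            if lf.taxon.label in set(present_leaves)
        ]
        if len(taxa) == 1:
            gain_node = tree.find_node_with_taxon_label(taxa[0].label)
        else:
            gain_node = tree.mrca(taxa=taxa)
    gain = "root" if gain_node is tree.seed_node else branch_id(gain_node)

    losses: set[str] = set()

    def all_absent(node: dendropy.Node) -> bool:
        return all(not presence[lf.taxon.label] for lf in node.leaf_iter())

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if all_absent(child):
                losses.add(branch_id(child))
            else:
                walk(child)

    walk(gain_node)
    return gain, losses


def _site_cols(matrix: pd.DataFrame, subset=None) -> list[tuple[str, str, int]]:
    cols = []
    for c in matrix.columns:
        gene, _, ordinal = str(c).rpartition(".")
        cols.append((c, gene, int(ordinal)))
    if subset is not None:
        want = {(g, o) for g, o in subset}
        cols = [t for t in cols if (t[1], t[2]) in want]
    return cols


def infer_min_events(
    tree: dendropy.Tree | str,
    matrix: pd.DataFrame,
    intron_subset: list[tuple[str, int]] | None = None,
    count_root_presence_as_gain: bool = False,
) -> tuple[list[LossEvent], int]:
    """Minimum number of block gain/loss events explaining a presence matrix.

    ``matrix`` is strains × sites with columns named ``gene.ordinal``;
    cells are truthy when the intron is present (the categorical state
    string ``"0"`` counts as absent).  Per-site Dollo assignments are
    merged per (branch, gene): sites form one block event when no site of
    the same gene that remains present in the branch's ancestral state lies
    between them (sites ancestrally absent do not break adjacency).  Gains
    on the root edge are ancestral presence, not events, unless
    ``count_root_presence_as_gain``.
    """
    tree = load_tree(tree)
    cols = _site_cols(matrix, intron_subset)
    if intron_subset is not None and len(cols) != len(intron_subset):
        have = {(g, o) for _, g, o in cols}
        raise ValueError(
            f"sites not in matrix: {sorted(set(intron_subset) - have)}"
        )

    def truthy(v) -> bool:
        return bool(v) and str(v) != "0"

    # per-site Dollo reconstruction
    per_site: dict[tuple[str, int], tuple[str | None, set[str]]] = {}
    for col, gene, ordinal in cols:
        presence = {s: truthy(matrix.loc[s, col]) for s in matrix.index}
        per_site[(gene, ordinal)] = dollo_loss_branches(tree, presence)

    # ancestral (parent-node) state per site per branch, by preorder replay
    node_state: dict[tuple[str, int], dict[int, bool]] = {
        k: {} for k in per_site
    }
    for (gene, ordinal), (gain, losses) in per_site.items():
        states = node_state[(gene, ordinal)]

        def walk(node: dendropy.Node, state: bool) -> None:
            bid = "root" if node is tree.seed_node else branch_id(node)
            if bid == gain:
                state = True
            if bid in losses:
                state = False
            states[id(node)] = state
            for child in node.child_nodes():
                walk(child, state)

        walk(tree.seed_node, False)

    # collect per-branch gain/loss site sets
    branch_nodes: dict[str, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        bid = "root" if node is tree.seed_node else branch_id(node)
        branch_nodes[bid] = node
    by_branch: dict[tuple[str, str, str], list[int]] = {}
    for (gene, ordinal), (gain, losses) in per_site.items():
        if gain is not None and gain != "root":
            by_branch.setdefault((gain, gene, "gain"), []).append(ordinal)
        elif gain == "root" and count_root_presence_as_gain:
            by_branch.setdefault(("root", gene, "gain"), []).append(ordinal)
        for b in losses:
            by_branch.setdefault((b, gene, "loss"), []).append(ordinal)

    ordinals_by_gene: dict[str, list[int]] = {}
    for _, gene, ordinal in cols:
        ordinals_by_gene.setdefault(gene, []).append(ordinal)

    events: list[LossEvent] = []
    for (bid, gene, kind), ordinals in sorted(by_branch.items()):
        node = branch_nodes[bid]
        parent = node.parent_node
        changing = sorted(set(ordinals))

        def parent_present(o: int) -> bool:
            if parent is None:
                return False  # root edge: ancestral context is the root state
            return node_state[(gene, o)].get(id(parent), False)

        # blocking sites: present in the ancestral state and not changing here
        blockers = {
            o
            for o in ordinals_by_gene[gene]
            if o not in changing and parent_present(o)
        }
        block = [changing[0]]
        for prev, cur in zip(changing, changing[1:]):
            if any(prev < b < cur for b in blockers):
                events.append(
                    LossEvent(bid, gene, frozenset(block), kind)
                )
                block = [cur]
            else:
                block.append(cur)
        events.append(LossEvent(bid, gene, frozenset(block), kind))

    events.sort(key=lambda e: (e.branch, e.gene, min(e.site_ordinals), e.kind))
    return events, len(events)
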