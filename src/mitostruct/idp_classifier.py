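"""Intron distribution pattern (IDP) classes, haplotypes and SNP regions.

An IDP class is the equivalence class of strains carrying exactly the same
intron state — presence/absence, type, subtype and insert signature — at
every variable intronic site.  This module selects the variable sites from
a categorical state matrix, partitions strains into IDP classes (labelled
IDP1..IDPk in phylogeny order when a tree is supplied), quantifies how well
the IDP partition matches a clade partition, collapses SNP haplotypes, and
classifies SNPs into exonic/intronic/intergenic regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .genome_io import AnnotatedGenome

__all__ = [
    "IDPClass",
    "CongruenceReport",
    "select_variable_sites",
    "assign_idp_classes",
    "idp_clade_congruence",
    "collapse_haplotypes",
    "classify_snp_regions",
    "read_vcf_positions",
]

MISSING_STATES = {"N", ".", "-", "?", ""}


@dataclass
class IDPClass:
    label: str
    state_vector: tuple[str, ...]
    members: list[str]
    cox1_intron_count: int = 0


@dataclass
class CongruenceReport:
    single_clade_class_count: int
    n_classes: int
    per_class_clade_spread: dict[str, int]
    adjusted_rand_index: float


def select_variable_sites(
    m: pd.DataFrame, scope: list[str] | None = None
) -> list[str]:
    """Columns with ≥2 distinct states among ``scope`` strains, in matrix order."""
    sub = m if scope is None else m.loc[list(scope)]
    if sub.empty:
        raise ValueError("scope is empty")
    return [c for c in m.columns if sub[c].nunique() >= 2]


def _tree_leaf_order(tree_source: str | dendropy.Tree) -> list[str]:
    if isinstance(tree_source, dendropy.Tree):
        tree = tree_source
    else:
        tree = dendropy.Tree.get(data=str(tree_source), schema="newick")
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def assign_idp_classes(
    m: pd.DataFrame,
    variable_sites: list[str],
    ordering_tree: str | dendropy.Tree | None = None,
    cox1_gene: str = "cox1",
) -> list[IDPClass]:
    """Partition strains into classes of identical states over variable sites.

    Labels IDP1..IDPk follow the first member's position in the tree's leaf
    sequence when ``ordering_tree`` is given (so classes appear in phylogeny
    order), else first occurrence in matrix row order.  ``cox1_intron_count``
    counts sites of the cox1 gene (over *all* matrix columns) present in the
    class's strains.
    """
    missing = [s for s in variable_sites if s not in m.columns]
    if missing:
        raise ValueError(f"variable sites not in matrix: {missing}")

    order = list(m.index)
    if ordering_tree is not None:
        leaf_order = _tree_leaf_order(ordering_tree)
        absent = set(m.index) - set(leaf_order)
        if absent:
            raise ValueError(f"tree is missing strains: {sorted(absent)}")
        rank = {s: i for i, s in enumerate(leaf_order)}
        order = sorted(m.index, key=lambda s: rank[s])

    groups: dict[tuple[str, ...], list[str]] = {}
    first_seen: dict[tuple[str, ...], int] = {}
    for i, strain in enumerate(order):
        vec = tuple(m.loc[strain, variable_sites]) if variable_sites else ()
        groups.setdefault(vec, []).append(strain)
        first_seen.setdefault(vec, i)

    cox1_cols = [c for c in m.columns if c.split(".")[0] == cox1_gene]
    classes = []
    for k, vec in enumerate(sorted(groups, key=lambda v: first_seen[v]), start=1):
        members = groups[vec]
        row = m.loc[members[0]]
        count = int(sum(row[c] != "0" for c in cox1_cols))
        classes.append(
            IDPClass(
                label=f"IDP{k}",
                state_vector=vec,
                members=members,
                cox1_intron_count=count,
            )
        )
    return classes


def idp_clade_congruence(
    idp: dict[str, str] | list[IDPClass], clades: dict[str, str]
) -> CongruenceReport:
    """Contingency-based congruence between the IDP and clade partitions.

    Reports how many IDP classes are confined to a single clade, the number
    of distinct clades each class spans, and the adjusted Rand index between
    the two partitions (permutation-model expectation).
    """
    if isinstance(idp, list):
        idp = {s: c.label for c in idp for s in c.members}
    if set(idp) != set(clades):
        raise ValueError(
            "IDP and clade partitions cover different strain sets: "
            f"{sorted(set(idp) ^ set(clades))}"
        )
    strains = sorted(idp)
    labels_idp = [idp[s] for s in strains]
    labels_clade = [clades[s] for s in strains]
    spread: dict[str, set] = {}
    for li, lc in zip(labels_idp, labels_clade):
        spread.setdefault(li, set()).add(lc)
    per_class = {li: len(cs) for li, cs in spread.items()}
    return CongruenceReport(
        single_clade_class_count=sum(1 for v in per_class.values() if v == 1),
        n_classes=len(per_class),
        per_class_clade_spread=per_class,
        adjusted_rand_index=float(adjusted_rand_score(labels_clade, labels_idp)),
    )


def collapse_haplotypes(
    aln: pd.DataFrame | np.ndarray,
    missing_policy: str = "drop_columns",
) -> tuple[list[list[str]], int]:
    """Group identical rows of a SNP state matrix into haplotypes.

    ``drop_columns`` removes every column containing a missing state
    (N/./-/?/empty) before grouping; ``strict`` treats missing as an
    ordinary state.  Returns ``(classes, n_haplotypes)`` where each class
    lists its row labels (row indices for array input).
    """
    if missing_policy not in ("drop_columns", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if isinstance(aln, np.ndarray):
        aln = pd.DataFrame(aln)
    df = aln.astype(str)
    if missing_policy == "drop_columns":
        keep = [c for c in df.columns if not df[c].isin(MISSING_STATES).any()]
        if not keep:
            raise ValueError("no columns left after dropping missing-state columns")
        df = df[keep]
    groups: dict[tuple, list] = {}
    for label, row in df.iterrows():
        groups.setdefault(tuple(row), []).append(label)
    classes = sorted(groups.values(), key=lambda mem: df.index.get_loc(mem[0]))
    return classes, len(classes)


# ---------------------------------------------------------------------------
# SNP region classification
# ---------------------------------------------------------------------------


def read_vcf_positions(path: str) -> list[int]:
    """0-based positions of records in a VCF file."""
    from cyvcf2 import VCF

    return [v.POS - 1 for v in VCF(path)]


def classify_snp_regions(
    positions: list[int], annotation: AnnotatedGenome
) -> dict[str, float]:
    """Fractions of SNP positions in exons, introns and intergenic regions.

    Exon precedence: a position inside an exonic segment of a CDS/rRNA/tRNA
    is an exon SNP even if an intron feature also covers it (intron segments
    are excluded from gene exonic segments by construction).  Positions are
    0-based; out-of-range positions raise with the record index.
    """
    n = len(annotation.sequence)
    exon_iv: list[tuple[int, int]] = []
    intron_iv: list[tuple[int, int]] = []
    for f in annotation.features:
        if f.kind in ("CDS", "rRNA", "tRNA"):
            exon_iv.extend(f.segments)
        elif f.kind == "intron":
            intron_iv.extend(f.segments)

    def _make_index(ivs):
        ivs = sorted((min(s, e), max(s, e)) for s, e in ivs)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        return starts, ends

    ex_s, ex_e = _make_index(exon_iv)
    in_s, in_e = _make_index(intron_iv)

    def _inside(pos, starts, ends):
        if len(starts) == 0:
            return False
        i = np.searchsorted(starts, pos, side="right") - 1
        # overlapping intervals possible; scan back a little
        while i >= 0:
            if starts[i] <= pos < ends[i]:
                return True
            if ends[i] <= pos and (i == 0 or ends[: i + 1].max() <= pos):
                break
            i -= 1
        return False

    counts = {"exon": 0, "intron": 0, "intergenic": 0}
    for idx, pos in enumerate(positions):
        if not (0 <= pos < n):
            raise ValueError(f"record {idx}: position {pos} outside [0, {n})")
        if _inside(pos, ex_s, ex_e):
            counts["exon"] += 1
        elif _inside(pos, in_s, in_e):
            counts["intron"] += 1
        else:
            counts["intergenic"] += 1
    total = max(1, len(positions))
    return {k: v / total for k, v in counts.items()}
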