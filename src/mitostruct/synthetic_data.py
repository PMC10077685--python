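"""Simulator of mitogenome structural evolution along a phylogeny.

Generates annotated circular mitogenomes that exercise every stage of the
package: a conserved gene scaffold (15 protein genes, 2 rRNAs, 20 tRNAs) at
reduced scale, a planted inverted-repeat (IRS) pair flanking an invertible
MIR segment carrying nad2/nad3/rrnL/rps3, intron presence evolving by gain,
single loss and correlated block loss along a tree, up to 8 plasmid-derived
dpo fragments gained and lost per lineage, and divergent intron types (with
declared subtype-diagnostic columns) at shared insertion sites.

The ground truth — per-leaf state matrix, event log, MIR orientations,
planted IRS coordinates and the true IDP partition — is returned alongside
and written as JSON by :func:`emit_genomes`, so pipeline output can be
compared against it exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .event_inference import branch_id, load_tree
from .genome_io import (
    AnnotatedGenome,
    Feature,
    StrainMeta,
    _revcomp,
    reverse_complement_genome,
    write_genbank,
    write_fasta_table,
    write_metadata_table,
)
from .intron_atlas import IntronSiteRegistry

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_evolution",
    "emit_genomes",
    "apply_subtype_declarations",
]

PROTEIN_GENES = [
    "cox1", "nad5", "cob", "cox2", "nad1", "nad4", "atp6", "atp8",
    "atp9", "cox3", "nad4L", "nad6", "nad2", "nad3", "rps3",
]
TRNAS = [f"trn{a}" for a in "ACDEFGHIKLMNPQRSTVWY"]  # 20 tRNA genes


@dataclass
class SimParams:
    """Simulation conditions; defaults emulate the structural processes of
    *Agaricus*-like mitogenomes at reduced genomic scale."""

    n_leaves: int = 12
    seed: int = 0
    gain_rate: float = 0.02  # gains per absent site per unit branch length
    loss_rate: float = 0.08  # losses per present site per unit branch length
    block_loss_prob: float = 0.4  # chance a loss extends to the next empty-context site
    dpo_gain_rate: float = 0.05
    dpo_loss_rate: float = 0.10
    inversion_rate: float = 0.15  # MIR flips per unit branch length
    subtype_switch_rate: float = 0.03
    at_content_target: float = 0.71
    exon_noise: float = 0.005  # substitutions per exon site per leaf
    intron_noise: float = 0.01  # within-type divergence of intron copies
    root_dpo: tuple[int, ...] = (0, 1, 3, 4, 5)  # fragments present at root
    root_orientation: str = "forward"
    scaffold_profile: str = "reduced"  # reduced (~45 kb) | full (~140 kb)

    def validate(self) -> None:
        for name in (
            "gain_rate", "loss_rate", "dpo_gain_rate", "dpo_loss_rate",
            "inversion_rate", "subtype_switch_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("block_loss_prob", "at_content_target", "exon_noise", "intron_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")


# ---------------------------------------------------------------------------
# scaffold: gene layout, intron types, dpo exemplars
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    return "".join(
        rng.choice(list("ATGC"), size=n, p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    )


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protected: set[int] | None = None
) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        if protected and int(i) in protected:
            continue
        alt = [b for b in "ACGT" if b != out[i]]
        out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


@dataclass
class _SiteSpec:
    gene: str
    ordinal: int
    intron_class: str
    type_seqs: dict[int, str]  # type index (1-based) -> exemplar sequence
    subtype_variants: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene, self.ordinal)


@dataclass
class Scaffold:
    exons: dict[str, list[str]]  # gene -> exon sequences (5'->3')
    sites: list[_SiteSpec]  # in registry order
    trna_seqs: dict[str, str]
    rrn_seqs: dict[str, str]
    single_seqs: dict[str, str]  # intron-less protein genes
    dpo_exemplars: list[str]
    spacer_len: int
    at: float

    def site(self, gene: str, ordinal: int) -> _SiteSpec:
        return next(s for s in self.sites if s.key == (gene, ordinal))

    def sites_of(self, gene: str) -> list[_SiteSpec]:
        return [s for s in self.sites if s.gene == gene]


# per-gene intron site counts; cox1 is the big reservoir, with multi-type
# sites and the subtype showcase on its last site
_REDUCED_INTRONS = {"cox1": 8, "nad5": 2, "cob": 6, "cox2": 6, "nad1": 1, "cox3": 1}
_FULL_INTRONS = {"cox1": 19, "nad5": 4, "cob": 9, "cox2": 7, "nad1": 3, "cox3": 2, "nad4": 2}


def build_scaffold(params: SimParams, rng: np.random.Generator) -> Scaffold:
    at = params.at_content_target
    full = params.scaffold_profile == "full"
    intron_counts = _FULL_INTRONS if full else _REDUCED_INTRONS
    exon_len = 220 if full else 150
    intron_len = lambda: int(rng.integers(400, 800))
    spacer = 600 if full else 400

    exons: dict[str, list[str]] = {}
    sites: list[_SiteSpec] = []
    for gene, n_introns in intron_counts.items():
        exons[gene] = [_random_seq(rng, exon_len, at) for _ in range(n_introns + 1)]
        for k in range(1, n_introns + 1):
            base = _random_seq(rng, intron_len(), at)
            # groupII at a minority of sites, as in fungal mitogenomes
            iclass = "groupII" if (k % 7 == 0) else "groupI"
            type_seqs = {1: base}
            # two sites per big gene carry a divergent second type (~30%)
            if gene == "cox1" and k in (3, n_introns):
                type_seqs[2] = _mutate(rng, base, 0.30)
            if gene == "cox1" and k == n_introns:
                type_seqs[3] = _mutate(rng, base, 0.35)
            spec = _SiteSpec(gene=gene, ordinal=k, intron_class=iclass, type_seqs=type_seqs)
            # subtype-diagnostic columns on the founding type of cox1's site 3:
            # one SNP and one 2-bp deletion distinguish subtypes A and B
            if gene == "cox1" and k == 3:
                p1, p2 = 60, 140
                spec.subtype_variants = [
                    (p1, base[p1], "A" if base[p1] != "A" else "G"),
                    (p2, base[p2 : p2 + 2], ""),
                ]
            sites.append(spec)

    single_seqs = {
        g: _random_seq(rng, int(rng.integers(300, 500)), at)
        for g in PROTEIN_GENES
        if g not in intron_counts
    }
    trna_seqs = {t: _random_seq(rng, 75, at) for t in TRNAS}
    rrn_seqs = {
        "rrnL": _random_seq(rng, 2400 if full else 1200, at),
        "rrnS": _random_seq(rng, 1500 if full else 900, at),
    }
    n_dpo = 8
    dpo_exemplars = [
        _random_seq(rng, int(rng.integers(300, 900)), at) for _ in range(n_dpo)
    ]
    return Scaffold(
        exons=exons,
        sites=sites,
        trna_seqs=trna_seqs,
        rrn_seqs=rrn_seqs,
        single_seqs=single_seqs,
        dpo_exemplars=dpo_exemplars,
        spacer_len=spacer,
        at=at,
    )


# ---------------------------------------------------------------------------
# evolution along the tree
# ---------------------------------------------------------------------------


def _state_str(spec: _SiteSpec, type_idx: int, subtype: str | None) -> str:
    label = f"{spec.ordinal}-{type_idx}"
    if subtype and type_idx == 1 and spec.subtype_variants:
        return f"{label}:{subtype}"
    return label


@dataclass
class SimTruth:
    newick: str
    state_matrix: pd.DataFrame  # leaves x sites, categorical states ("0"=absent)
    events: list[dict]
    mir_orientation: dict[str, str]
    dpo_sets: dict[str, tuple[int, ...]]
    partition: list[list[str]]  # true IDP partition over variable sites
    irs_coords: dict[str, list[list[int]]] = field(default_factory=dict)
    scaffold: Scaffold | None = None
    params: SimParams | None = None

    @property
    def tree(self) -> dendropy.Tree:
        return load_tree(self.newick)


def _random_tree(n_leaves: int, seed: int) -> dendropy.Tree:
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_leaves,
        ploidy=1,
        population_size=1.0,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    tree = dendropy.Tree.get(
        data=ts.first().as_newick(), schema="newick", preserve_underscores=True
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{i + 1:02d}"
    return tree


def _truth_partition(matrix: pd.DataFrame) -> list[list[str]]:
    variable = [c for c in matrix.columns if matrix[c].nunique() >= 2]
    groups: dict[tuple, list[str]] = {}
    for strain in matrix.index:
        groups.setdefault(tuple(matrix.loc[strain, variable]), []).append(strain)
    return sorted(groups.values(), key=lambda g: g[0])


def simulate_evolution(
    tree: dendropy.Tree | str | None, params: SimParams
) -> SimTruth:
    """Evolve intron, dpo and MIR-orientation states along a tree.

    Events are drawn as Poisson processes per branch; block losses extend
    to the adjacent present site of the same gene with probability
    ``block_loss_prob`` per additional site.  Fully reproducible from
    ``params.seed`` (the tree too, when none is given).
    """
    params.validate()
    scaffold = build_scaffold(params, np.random.default_rng([params.seed, 17]))
    if tree is None:
        tree = _random_tree(params.n_leaves, params.seed + 1)
    else:
        tree = load_tree(tree)
    rng = np.random.default_rng([params.seed, 29])

    site_keys = [s.key for s in scaffold.sites]
    root_state = {
        s.key: _state_str(s, 1, "A" if s.subtype_variants else None)
        for s in scaffold.sites
    }
    root_dpo = frozenset(params.root_dpo)
    n_frags = len(scaffold.dpo_exemplars)

    events: list[dict] = []
    leaf_states: dict[str, dict] = {}
    leaf_orient: dict[str, str] = {}
    leaf_dpo: dict[str, tuple[int, ...]] = {}

    def ordinal_of(key):  # adjacency is within-gene ordinal order
        return key[1]

    def evolve(node, state, dpo, orient):
        state = dict(state)
        dpo = set(dpo)
        blen = node.edge.length or 0.0
        bid = "root" if node.parent_node is None else branch_id(node)
        if node.parent_node is not None and blen > 0:
            # --- intron losses, with correlated block extension
            present = [k for k in site_keys if state[k] != "0"]
            n_loss = rng.poisson(params.loss_rate * blen * len(present))
            for _ in range(min(n_loss, len(present))):
                present = [k for k in site_keys if state[k] != "0"]
                if not present:
                    break
                k0 = present[rng.integers(len(present))]
                block = [k0]
                gene = k0[0]
                direction = 1 if rng.random() < 0.5 else -1
                cur = k0
                while rng.random() < params.block_loss_prob:
                    gene_present = sorted(
                        (k for k in site_keys if k[0] == gene and state[k] != "0" and k not in block),
                        key=ordinal_of,
                    )
                    nxt = None
                    if direction > 0:
                        after = [k for k in gene_present if ordinal_of(k) > ordinal_of(cur)]
                        nxt = after[0] if after else None
                    else:
                        before = [k for k in gene_present if ordinal_of(k) < ordinal_of(cur)]
                        nxt = before[-1] if before else None
                    if nxt is None:
                        break
                    block.append(nxt)
                    cur = nxt
                for k in block:
                    state[k] = "0"
                events.append(
                    {"branch": bid, "kind": "loss", "gene": gene,
                     "sites": sorted(ordinal_of(k) for k in block)}
                )
            # --- intron gains
            absent = [k for k in site_keys if state[k] == "0"]
            n_gain = rng.poisson(params.gain_rate * blen * len(absent))
            for _ in range(min(n_gain, len(absent))):
                absent = [k for k in site_keys if state[k] == "0"]
                if not absent:
                    break
                k0 = absent[rng.integers(len(absent))]
                spec = scaffold.site(*k0)
                tidx = sorted(spec.type_seqs)[rng.integers(len(spec.type_seqs))]
                state[k0] = _state_str(spec, tidx, "A" if spec.subtype_variants else None)
                events.append(
                    {"branch": bid, "kind": "gain", "gene": k0[0], "sites": [k0[1]]}
                )
            # --- subtype switches at sites with declared variant columns
            switchable = [
                s.key for s in scaffold.sites
                if s.subtype_variants and state[s.key].endswith((":A", ":B"))
            ]
            n_sw = rng.poisson(params.subtype_switch_rate * blen * len(switchable))
            for _ in range(min(n_sw, len(switchable))):
                k0 = switchable[rng.integers(len(switchable))]
                cur = state[k0]
                state[k0] = cur[:-1] + ("B" if cur.endswith("A") else "A")
                events.append(
                    {"branch": bid, "kind": "subtype_switch", "gene": k0[0], "sites": [k0[1]]}
                )
            # --- dpo gain/loss
            n_dl = rng.poisson(params.dpo_loss_rate * blen * len(dpo))
            for _ in range(min(n_dl, len(dpo))):
                if not dpo:
                    break
                f = sorted(dpo)[rng.integers(len(dpo))]
                dpo.discard(f)
                events.append({"branch": bid, "kind": "dpo_loss", "fragment": f})
            missing = [f for f in range(n_frags) if f not in dpo]
            n_dg = rng.poisson(params.dpo_gain_rate * blen * len(missing))
            for _ in range(min(n_dg, len(missing))):
                missing = [f for f in range(n_frags) if f not in dpo]
                if not missing:
                    break
                f = missing[rng.integers(len(missing))]
                dpo.add(f)
                events.append({"branch": bid, "kind": "dpo_gain", "fragment": f})
            # --- MIR inversions
            n_flip = rng.poisson(params.inversion_rate * blen)
            if n_flip % 2:
                orient = "reverse" if orient == "forward" else "forward"
            for _ in range(n_flip):
                events.append({"branch": bid, "kind": "inversion"})

        if node.is_leaf():
            label = node.taxon.label
            leaf_states[label] = state
            leaf_orient[label] = orient
            leaf_dpo[label] = tuple(sorted(dpo))
        else:
            for child in node.child_nodes():
                evolve(child, state, dpo, orient)

    evolve(tree.seed_node, root_state, root_dpo, params.root_orientation)

    cols = [f"{g}.{o}" for g, o in site_keys]
    matrix = pd.DataFrame.from_dict(
        {
            leaf: {f"{g}.{o}": st[(g, o)] for g, o in site_keys}
            for leaf, st in leaf_states.items()
        },
        orient="index",
        columns=cols,
    ).sort_index()
    matrix.index.name = "strain_id"

    return SimTruth(
        newick=tree.as_string(schema="newick").strip(),
        state_matrix=matrix,
        events=events,
        mir_orientation=leaf_orient,
        dpo_sets=leaf_dpo,
        partition=_truth_partition(matrix),
        scaffold=scaffold,
        params=params,
    )


# ---------------------------------------------------------------------------
# genome realization
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.features: list[Feature] = []
        self.pos = 0

    def add_seq(self, seq: str) -> int:
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        return start

    def add_feature(self, name, kind, strand, segments, quals=None) -> None:
        self.features.append(
            Feature(name=name, kind=kind, strand=strand, segments=list(segments),
                    qualifiers=dict(quals or {}))
        )

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _realize_intron(
    scaffold: Scaffold, spec: _SiteSpec, state: str, rng: np.random.Generator,
    noise: float,
) -> str:
    label, _, subtype = state.partition(":")
    tidx = int(label.split("-")[1])
    seq = scaffold.site(spec.gene, spec.ordinal).type_seqs[tidx]
    protected: set[int] = set()
    if subtype and spec.subtype_variants:
        if subtype == "B":
            out = seq
            for pos, ref, alt in sorted(spec.subtype_variants, key=lambda v: -v[0]):
                out = out[:pos] + alt + out[pos + len(ref):]
            seq = out
        for pos, ref, alt in spec.subtype_variants:
            protected.update(range(max(0, pos - 4), pos + max(len(ref), len(alt)) + 4))
    return _mutate(rng, seq, noise, protected)


def _add_gene_with_introns(
    b: _Builder, scaffold: Scaffold, gene: str, state_row: dict[str, str],
    rng: np.random.Generator, params: SimParams,
) -> None:
    exon_seqs = scaffold.exons[gene]
    specs = scaffold.sites_of(gene)
    exon_segs = []
    for i, ex in enumerate(exon_seqs):
        s = b.add_seq(_mutate(rng, ex, params.exon_noise))
        exon_segs.append((s, b.pos))
        if i < len(specs):
            spec = specs[i]
            state = state_row[f"{gene}.{spec.ordinal}"]
            if state != "0":
                iseq = _realize_intron(scaffold, spec, state, rng, params.intron_noise)
                s2 = b.add_seq(iseq)
                b.add_feature(
                    f"{gene}-i{spec.ordinal}", "intron", "+", [(s2, b.pos)],
                    {"host_gene": gene, "intron_class": spec.intron_class},
                )
    b.add_feature(gene, "CDS", "+", exon_segs)


def _spacer(b: _Builder, scaffold: Scaffold, rng: np.random.Generator) -> None:
    b.add_seq(_random_seq(rng, scaffold.spacer_len, scaffold.at))


# tRNA allocation: 8 in each IRS copy, 9 inside the MIR, 3 elsewhere
_IRS_TRNAS = TRNAS[:8]
_MIR_TRNAS = TRNAS[8:17]
_FREE_TRNAS = TRNAS[17:]


def _build_mir_block(
    scaffold: Scaffold, state_row, dpo_set, orientation, rng, params
) -> tuple[str, list[Feature]]:
    mb = _Builder()
    _spacer(mb, scaffold, rng)
    for f in sorted(dpo_set):
        s = mb.add_seq(scaffold.dpo_exemplars[f])
        mb.add_feature(f"dpo-f{f + 1}", "dpo", "+", [(s, mb.pos)])
        _spacer(mb, scaffold, rng)
    for t in _MIR_TRNAS:
        s = mb.add_seq(scaffold.trna_seqs[t])
        mb.add_feature(t, "tRNA", "+", [(s, mb.pos)])
    _spacer(mb, scaffold, rng)
    for gene in ("nad2", "nad3"):
        s = mb.add_seq(_mutate(rng, scaffold.single_seqs[gene], params.exon_noise))
        mb.add_feature(gene, "CDS", "+", [(s, mb.pos)])
        _spacer(mb, scaffold, rng)
    s = mb.add_seq(scaffold.rrn_seqs["rrnL"])
    mb.add_feature("rrnL", "rRNA", "+", [(s, mb.pos)])
    _spacer(mb, scaffold, rng)
    s = mb.add_seq(_mutate(rng, scaffold.single_seqs["rps3"], params.exon_noise))
    mb.add_feature("rps3", "CDS", "+", [(s, mb.pos)])
    _spacer(mb, scaffold, rng)
    seq, feats = mb.sequence, mb.features
    if orientation == "reverse":
        tmp = AnnotatedGenome(strain_id="_mir", sequence=seq, features=feats)
        tmp = reverse_complement_genome(tmp)
        seq, feats = tmp.sequence, tmp.features
    return seq, feats


def realize_genome(
    strain_id: str,
    scaffold: Scaffold,
    state_row: dict[str, str],
    dpo_set: tuple[int, ...],
    orientation: str,
    params: SimParams,
    rng: np.random.Generator,
    metadata: StrainMeta | None = None,
) -> tuple[AnnotatedGenome, dict]:
    """Assemble one leaf's genome; returns it plus planted-structure coords."""
    b = _Builder()
    # anchor gene first: the genome is emitted in normalized orientation
    for gene in ("cox1", "nad5", "cob", "cox2", "nad1"):
        if gene in scaffold.exons:
            _add_gene_with_introns(b, scaffold, gene, state_row, rng, params)
        else:
            s = b.add_seq(_mutate(rng, scaffold.single_seqs[gene], params.exon_noise))
            b.add_feature(gene, "CDS", "+", [(s, b.pos)])
        _spacer(b, scaffold, rng)
    for gene in ("nad4", "atp6", "atp8", "atp9", "cox3", "nad4L", "nad6"):
        if gene in scaffold.exons:
            _add_gene_with_introns(b, scaffold, gene, state_row, rng, params)
        else:
            s = b.add_seq(_mutate(rng, scaffold.single_seqs[gene], params.exon_noise))
            b.add_feature(gene, "CDS", "+", [(s, b.pos)])
        _spacer(b, scaffold, rng)
    for t in _FREE_TRNAS:
        s = b.add_seq(scaffold.trna_seqs[t])
        b.add_feature(t, "tRNA", "+", [(s, b.pos)])
        _spacer(b, scaffold, rng)
    s = b.add_seq(scaffold.rrn_seqs["rrnS"])
    b.add_feature("rrnS", "rRNA", "+", [(s, b.pos)])
    _spacer(b, scaffold, rng)

    # IRS copy A (8 tRNAs), forward
    irs_parts: list[tuple[str, int, int]] = []
    irs_start = b.pos
    for t in _IRS_TRNAS:
        s = b.add_seq(scaffold.trna_seqs[t])
        irs_parts.append((t, s, b.pos))
        b.add_seq(_random_seq(rng, 20, scaffold.at))
    irs_a = (irs_start, b.pos)
    irs_seq = b.sequence[irs_start:]

    # MIR block (dpo fragments, 9 tRNAs, nad2/nad3/rrnL/rps3)
    mir_seq, mir_feats = _build_mir_block(
        scaffold, state_row, dpo_set, orientation, rng, params
    )
    offset = b.add_seq(mir_seq)
    for f in mir_feats:
        b.add_feature(
            f.name, f.kind, f.strand,
            [(s0 + offset, e0 + offset) for s0, e0 in f.segments],
            f.qualifiers,
        )
    mir_span = (offset, b.pos)

    # IRS copy B: exact reverse complement of copy A
    b_start = b.add_seq(_revcomp(irs_seq))
    irs_len = len(irs_seq)
    for t, s0, e0 in irs_parts:
        lo = b_start + (irs_len - (e0 - irs_start))
        hi = b_start + (irs_len - (s0 - irs_start))
        b.add_feature(t, "tRNA", "-", [(lo, hi)])
    irs_b = (b_start, b.pos)
    _spacer(b, scaffold, rng)

    g = AnnotatedGenome(
        strain_id=strain_id,
        sequence=b.sequence,
        features=b.features,
        metadata=metadata or StrainMeta(),
    )
    planted = {"irs_a": list(irs_a), "irs_b": list(irs_b), "mir": list(mir_span)}
    return g, planted


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def _leaf_clades(tree: dendropy.Tree) -> dict[str, str]:
    clades = {}
    for i, child in enumerate(tree.seed_node.child_nodes()):
        name = f"clade{chr(ord('A') + i)}"
        for lf in child.leaf_iter():
            clades[lf.taxon.label] = name
    return clades


def emit_genomes(
    truth: SimTruth, params: SimParams, outdir: str | Path
) -> dict[str, AnnotatedGenome]:
    """Write GenBank + FASTA/table per leaf, a reference genome realizing
    the root state (all sites occupied, all dpo fragments, forward MIR),
    the metadata table, the tree and the ground-truth JSON.

    Returns the in-memory genomes keyed by strain id (reference = "REF").
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaffold = truth.scaffold
    assert scaffold is not None
    tree = truth.tree
    clades = _leaf_clades(tree)

    genomes: dict[str, AnnotatedGenome] = {}
    ref_state = {
        f"{s.gene}.{s.ordinal}": _state_str(s, 1, "A" if s.subtype_variants else None)
        for s in scaffold.sites
    }
    noiseless = SimParams(**{**asdict(params), "exon_noise": 0.0, "intron_noise": 0.0})
    ref, _ = realize_genome(
        "REF", scaffold, ref_state,
        tuple(range(len(scaffold.dpo_exemplars))), "forward",
        noiseless, np.random.default_rng([params.seed, 7919]),
        StrainMeta(clade="reference", variety="unknown", origin="synthetic",
                   cultivar_status="unknown"),
    )
    genomes["REF"] = ref

    metas: dict[str, StrainMeta] = {"REF": ref.metadata}
    for i, strain in enumerate(truth.state_matrix.index):
        meta = StrainMeta(
            clade=clades.get(strain, "unknown"), variety="bisporus",
            origin="synthetic", cultivar_status="wild",
        )
        g, planted = realize_genome(
            strain, scaffold,
            dict(truth.state_matrix.loc[strain]),
            truth.dpo_sets[strain], truth.mir_orientation[strain],
            params, np.random.default_rng([params.seed, 104729, i]), meta,
        )
        genomes[strain] = g
        truth.irs_coords[strain] = [planted["irs_a"], planted["irs_b"]]
        metas[strain] = meta

    for sid, g in genomes.items():
        write_genbank(g, outdir / f"{sid}.gbk")
        write_fasta_table(g, outdir / f"{sid}.fasta", outdir / f"{sid}.features.tsv")
    write_metadata_table(metas, outdir / "metadata.tsv")
    (outdir / "tree.nwk").write_text(truth.newick + "\n")

    subtype_decl = {
        f"{s.gene}.{s.ordinal}": {
            "type_label": f"{s.ordinal}-1",
            "variants": [list(v) for v in s.subtype_variants],
        }
        for s in scaffold.sites
        if s.subtype_variants
    }
    truth_payload = {
        "newick": truth.newick,
        "states": {
            strain: dict(truth.state_matrix.loc[strain])
            for strain in truth.state_matrix.index
        },
        "events": truth.events,
        "mir_orientation": truth.mir_orientation,
        "dpo_sets": {k: list(v) for k, v in truth.dpo_sets.items()},
        "partition": truth.partition,
        "irs_coords": truth.irs_coords,
        "subtype_variants": subtype_decl,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(params).items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    return genomes


def apply_subtype_declarations(
    registry: IntronSiteRegistry, declarations: dict
) -> None:
    """Attach curated subtype-diagnostic columns to registry exemplars.

    ``declarations`` maps ``"gene.ordinal"`` to ``{"type_label": ...,
    "variants": [[pos, ref, alt], ...]}`` (the format written to
    ``truth.json`` by :func:`emit_genomes`).
    """
    for key, decl in declarations.items():
        gene, _, ordinal = key.rpartition(".")
        site = registry.get(gene, int(ordinal))
        label = decl["type_label"]
        if label in site.known_types:
            site.known_types[label].subtype_variants = [
                (int(p), r, a) for p, r, a in decl["variants"]
            ]
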