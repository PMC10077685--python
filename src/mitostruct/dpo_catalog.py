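"""Catalog and per-strain profiling of plasmid-derived *dpo* fragments.

Fragments of a plasmid DNA-polymerase gene (*dpo*) integrate at various
positions in *Agaricus* mitogenomes; their presence/absence combinations
are nearly fixed within clades and differ between clades.  This module
clusters dpo-annotated segments from a set of genomes into a named catalog
(dpo1..dpoN, named by genomic position rank in a designated naming genome),
searches each catalog exemplar against every genome on both strands, and
summarizes presence per clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .genome_io import AnnotatedGenome, StrainMeta, _revcomp, feature_sequence

__all__ = [
    "DpoFragment",
    "DpoHit",
    "DpoProfile",
    "build_dpo_catalog",
    "profile_genome_dpo",
    "clade_dpo_summary",
]

DEFAULT_MERGE_ID = 0.90  # single-linkage clustering threshold for the catalog
DEFAULT_ASSIGN_ID = 0.75  # minimum identity to call a genomic hit
DEFAULT_MIN_COVER = 0.60  # minimum exemplar coverage of a hit


@dataclass
class DpoFragment:
    fragment_id: str
    exemplar_seq: str
    canonical_rank: int


@dataclass(frozen=True)
class DpoHit:
    fragment_id: str
    segment: tuple[int, int]
    strand: str
    identity: float
    in_repeat: bool = False


@dataclass
class DpoProfile:
    strain_id: str
    hits: list[DpoHit] = field(default_factory=list)

    def fragment_ids(self, include_in_repeat: bool = False) -> list[str]:
        return [
            h.fragment_id
            for h in self.hits
            if include_in_repeat or not h.in_repeat
        ]


def _pair_identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _best_orientation_identity(a: str, b: str) -> float:
    return max(_pair_identity(a, b), _pair_identity(a, _revcomp(b)))


def build_dpo_catalog(
    genomes: list[AnnotatedGenome],
    merge_id: float = DEFAULT_MERGE_ID,
    naming_genome: str | None = None,
) -> list[DpoFragment]:
    """Cluster all dpo-annotated segments into a named fragment catalog.

    Single-linkage clustering at ``merge_id`` identity (strand-agnostic);
    the longest member of each cluster becomes the exemplar.  Fragment names
    dpo1..dpoN follow genomic position rank in ``naming_genome`` (default:
    the first genome carrying any dpo feature), then discovery order for
    clusters absent from it.
    """
    members: list[tuple[str, int, str]] = []  # (strain, start, seq)
    for g in genomes:
        for f in g.features_of_kind("dpo"):
            members.append((g.strain_id, f.start, feature_sequence(g, f)))
    if not members:
        warnings.warn("no dpo-annotated features in any genome; empty catalog")
        return []

    # single-linkage via union-find
    parent = list(range(len(members)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if find(i) == find(j):
                continue
            if _best_orientation_identity(members[i][2], members[j][2]) >= merge_id:
                parent[find(j)] = find(i)

    clusters: dict[int, list[int]] = {}
    for i in range(len(members)):
        clusters.setdefault(find(i), []).append(i)

    if naming_genome is None:
        with_dpo = [g.strain_id for g in genomes if g.features_of_kind("dpo")]
        naming_genome = with_dpo[0]

    # rank clusters: position of first member in the naming genome, then
    # discovery order (first member overall)
    ranked = []
    for root, idxs in clusters.items():
        in_naming = sorted(
            m[1] for m in (members[i] for i in idxs) if m[0] == naming_genome
        )
        pos_rank = (0, in_naming[0]) if in_naming else (1, min(idxs))
        exemplar = max((members[i][2] for i in idxs), key=len)
        ranked.append((pos_rank, exemplar))
    ranked.sort(key=lambda t: t[0])
    return [
        DpoFragment(fragment_id=f"dpo{r + 1}", exemplar_seq=seq, canonical_rank=r + 1)
        for r, (_, seq) in enumerate(ranked)
    ]


def _find_hits(
    seq: str, exemplar: str, max_dist: int
) -> list[tuple[int, int, int]]:
    """Non-overlapping infix hits of ``exemplar`` in ``seq``: (start, end, dist)."""
    res = edlib.align(exemplar, seq, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] == -1:
        return []
    # edlib returns many overlapping co-optimal locations; greedily keep
    # non-overlapping ones (locations are sorted by start)
    hits: list[tuple[int, int, int]] = []
    for s, e in res["locations"]:
        e = e + 1  # edlib end is inclusive
        if hits and s < hits[-1][1]:
            continue
        hits.append((s, e, res["editDistance"]))
    return hits


def profile_genome_dpo(
    g: AnnotatedGenome,
    catalog: list[DpoFragment],
    assign_id: float = DEFAULT_ASSIGN_ID,
    min_cover: float = DEFAULT_MIN_COVER,
    repeats=None,
) -> DpoProfile:
    """Locate every catalog fragment in a genome, both strands.

    A hit requires alignment identity ≥ ``assign_id`` computed over the
    exemplar length; hits covering less than ``min_cover`` of the exemplar
    are discarded.  When hits to two fragments overlap, the higher-identity
    one wins (with a warning).  ``repeats`` (optional list of
    :class:`~mitostruct.repeat_structure.RepeatPair`) marks hits lying
    inside an IRS copy as ``in_repeat``.
    """
    if not catalog:
        raise ValueError("dpo catalog is empty")
    seq = g.sequence
    raw: list[DpoHit] = []
    for frag in catalog:
        max_dist = int((1.0 - assign_id) * len(frag.exemplar_seq))
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            for start, end, dist in _find_hits(s, frag.exemplar_seq, max_dist):
                ident = 1.0 - dist / len(frag.exemplar_seq)
                if (end - start) / len(frag.exemplar_seq) < min_cover:
                    continue
                if strand == "-":
                    start, end = len(seq) - end, len(seq) - start
                raw.append(
                    DpoHit(
                        fragment_id=frag.fragment_id,
                        segment=(start, end),
                        strand=strand,
                        identity=ident,
                    )
                )

    # resolve overlaps between fragments: keep higher identity
    raw.sort(key=lambda h: (-h.identity, h.segment))
    kept: list[DpoHit] = []
    for h in raw:
        clash = next(
            (
                q
                for q in kept
                if min(h.segment[1], q.segment[1]) > max(h.segment[0], q.segment[0])
            ),
            None,
        )
        if clash is not None:
            if clash.fragment_id != h.fragment_id:
                warnings.warn(
                    f"{g.strain_id}: overlapping dpo hits "
                    f"{clash.fragment_id}/{h.fragment_id}; keeping "
                    f"{clash.fragment_id} (higher identity)"
                )
            continue
        kept.append(h)

    if repeats:
        spans = [p.copy_a for p in repeats] + [p.copy_b for p in repeats]
        kept = [
            DpoHit(
                h.fragment_id,
                h.segment,
                h.strand,
                h.identity,
                in_repeat=any(
                    h.segment[0] >= lo and h.segment[1] <= hi for lo, hi in spans
                ),
            )
            for h in kept
        ]

    kept.sort(key=lambda h: h.segment)
    return DpoProfile(strain_id=g.strain_id, hits=kept)


def clade_dpo_summary(
    profiles: list[DpoProfile],
    meta: dict[str, StrainMeta],
    catalog: list[DpoFragment],
    include_in_repeat: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clade presence fractions and the ≥0.5 consensus calls.

    Returns ``(fractions, consensus)`` DataFrames indexed by clade with one
    column per catalog fragment.  Strains with no or unknown clade label are
    grouped under ``"unknown"``.
    """
    frag_ids = [f.fragment_id for f in catalog]
    rows = []
    for p in profiles:
        clade = meta.get(p.strain_id, StrainMeta()).clade or "unknown"
        present = set(p.fragment_ids(include_in_repeat=include_in_repeat))
        rows.append({"clade": clade, **{fid: fid in present for fid in frag_ids}})
    df = pd.DataFrame(rows)
    fractions = df.groupby("clade")[frag_ids].mean()
    consensus = fractions >= 0.5
    return fractions, consensus
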