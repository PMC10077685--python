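"""Homologous intron-site registry and per-strain intron mapping.

Mobile group I/II introns in fungal mitochondria insert at defined positions
within host genes.  Two introns in two strains are considered homologous
when they sit at the same *spliced coordinate* — the position within the
host gene's concatenated exonic sequence.  This module builds a registry of
such sites from a reference genome, maps every query genome's introns onto
it (registering novel sites when needed), classifies intron sequences into
types by global-alignment identity against per-site exemplars, calls
subtypes at declared variant columns, and flags structural anomalies
(internal insertions, degenerate/truncated copies).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd
from Bio import Align

from .genome_io import (
    AnnotatedGenome,
    Feature,
    GenomeValidationError,
    feature_sequence,
    rotate_genome,
)

__all__ = [
    "TypeExemplar",
    "IntronSite",
    "IntronObservation",
    "IntronSiteRegistry",
    "build_site_registry",
    "map_introns",
    "classify_intron_type",
    "detect_intron_anomalies",
    "intron_spliced_position",
    "observation_state",
    "observations_to_matrix",
    "write_state_matrix",
    "read_state_matrix",
]

DEFAULT_TOL = 6  # nt tolerance for calling two insertion points homologous
DEFAULT_ID_THRESHOLD = 0.90  # global identity above which two introns share a type
DEFAULT_INSERT_MIN = 15  # nt; shorter query-only runs are alignment slippage
DEFAULT_COVER_MIN = 0.80  # exemplar coverage below this flags a degenerate copy


@dataclass
class TypeExemplar:
    type_label: str
    exemplar_seq: str
    # declared diagnostic columns: (position in exemplar, ref_state, alt_state);
    # the joint state over these columns defines the subtype (all-ref -> "A",
    # all-alt -> "B")
    subtype_variants: list[tuple[int, str, str]] = field(default_factory=list)


@dataclass
class IntronSite:
    gene: str
    ordinal: int
    spliced_pos: int
    intron_class: str = "unknown"  # groupI | groupII | unknown
    known_types: dict[str, TypeExemplar] = field(default_factory=dict)
    novel: bool = False

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene, self.ordinal)


@dataclass
class IntronObservation:
    strain_id: str
    site: tuple[str, int]
    present: bool
    type_label: str | None = None
    subtype_label: str | None = None
    length: int = 0
    inserts: list[tuple[int, int]] = field(default_factory=list)
    degenerate: bool = False
    novel_site: bool = False


class IntronSiteRegistry:
    """Ordered collection of homologous intron insertion sites.

    Sites are keyed by ``(gene, ordinal)``; within a gene, ordinals follow
    5'→3' order of the spliced insertion positions in the reference.  Sites
    discovered only in query genomes are appended with the next free ordinal
    of their gene (stable suffixing: reference ordinals never change) and
    flagged ``novel``.
    """

    def __init__(self, gene_order: list[str] | None = None) -> None:
        self.gene_order: list[str] = gene_order or []
        self._sites: dict[tuple[str, int], IntronSite] = {}

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._sites)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._sites

    def get(self, gene: str, ordinal: int) -> IntronSite:
        return self._sites[(gene, ordinal)]

    @property
    def sites(self) -> list[IntronSite]:
        """All sites in registry order (gene order, then spliced position)."""

        def sort_key(s: IntronSite):
            gi = (
                self.gene_order.index(s.gene)
                if s.gene in self.gene_order
                else len(self.gene_order)
            )
            return (gi, s.gene, s.spliced_pos, s.ordinal)

        return sorted(self._sites.values(), key=sort_key)

    def sites_for(self, gene: str) -> list[IntronSite]:
        return [s for s in self.sites if s.gene == gene]

    # -- mutation ----------------------------------------------------------

    def add(self, site: IntronSite) -> None:
        if site.key in self._sites:
            raise GenomeValidationError(f"duplicate intron site {site.key}")
        if site.gene not in self.gene_order:
            self.gene_order.append(site.gene)
        self._sites[site.key] = site

    def match(self, gene: str, spliced_pos: int, tol: int) -> IntronSite | None:
        """Nearest site of ``gene`` within ``tol`` of ``spliced_pos``."""
        best, best_d = None, tol + 1
        for s in self.sites_for(gene):
            d = abs(s.spliced_pos - spliced_pos)
            if d < best_d:
                best, best_d = s, d
        return best

    def augment(
        self, gene: str, spliced_pos: int, tol: int, intron_class: str = "unknown"
    ) -> IntronSite:
        """Return the homologous site, registering a novel one if absent."""
        hit = self.match(gene, spliced_pos, tol)
        if hit is not None:
            return hit
        existing = self.sites_for(gene)
        ordinal = max((s.ordinal for s in existing), default=0) + 1
        site = IntronSite(
            gene=gene,
            ordinal=ordinal,
            spliced_pos=spliced_pos,
            intron_class=intron_class,
            novel=True,
        )
        self.add(site)
        return site

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "gene_order": self.gene_order,
            "sites": [
                {
                    "gene": s.gene,
                    "ordinal": s.ordinal,
                    "spliced_pos": s.spliced_pos,
                    "intron_class": s.intron_class,
                    "novel": s.novel,
                    "types": [
                        {
                            "type_label": t.type_label,
                            "exemplar_seq": t.exemplar_seq,
                            "subtype_variants": [list(v) for v in t.subtype_variants],
                        }
                        for t in s.known_types.values()
                    ],
                }
                for s in self.sites
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "IntronSiteRegistry":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        payload = json.loads(text)
        reg = cls(gene_order=list(payload["gene_order"]))
        for sd in payload["sites"]:
            site = IntronSite(
                gene=sd["gene"],
                ordinal=sd["ordinal"],
                spliced_pos=sd["spliced_pos"],
                intron_class=sd.get("intron_class", "unknown"),
                novel=sd.get("novel", False),
            )
            for td in sd.get("types", []):
                site.known_types[td["type_label"]] = TypeExemplar(
                    type_label=td["type_label"],
                    exemplar_seq=td["exemplar_seq"],
                    subtype_variants=[
                        (int(a), b, c) for a, b, c in td.get("subtype_variants", [])
                    ],
                )
            reg.add(site)
        return reg


# ---------------------------------------------------------------------------
# spliced coordinates
# ---------------------------------------------------------------------------


def intron_spliced_position(gene: Feature, intron: Feature) -> int:
    """Insertion point of ``intron`` in ``gene``'s spliced coordinates.

    Equals the number of exonic bases 5' of the intron in gene orientation.
    The intron must lie within the gene's genomic span.
    """
    i_lo, i_hi = intron.span()
    g_lo, g_hi = gene.span()
    if i_lo < g_lo or i_hi > g_hi:
        raise GenomeValidationError(
            f"intron {intron.name!r} [{i_lo},{i_hi}) outside host gene "
            f"{gene.name!r} span [{g_lo},{g_hi})"
        )
    pos = 0
    for s, e in gene.segments:  # 5'→3' order
        if gene.strand == "+":
            if e <= i_lo:
                pos += e - s
            elif s < i_lo:
                pos += i_lo - s
        else:
            if s >= i_hi:
                pos += e - s
            elif e > i_hi:
                pos += e - i_hi
    return pos


# ---------------------------------------------------------------------------
# registry construction and mapping
# ---------------------------------------------------------------------------


def _unwrap_origin(g: AnnotatedGenome) -> AnnotatedGenome:
    """Rotate a circular genome so no feature crosses the origin.

    Spliced-coordinate arithmetic assumes contiguous gene loci; after an
    arbitrary rotation a gene may be split across position 0.  Rotating to
    any feature-free position restores contiguity without changing any
    spliced coordinate.
    """
    n = len(g.sequence)
    covered_zero = any(s == 0 for f in g.features for s, _ in f.segments) and any(
        e == n for f in g.features for _, e in f.segments
    )
    if not g.circular or not covered_zero:
        return g
    ends = sorted(e for f in g.features for _, e in f.segments)
    for e in ends:
        if not any(s <= e % n < en for f in g.features for s, en in f.segments):
            return rotate_genome(g, e % n)
    raise GenomeValidationError(
        f"{g.strain_id}: no feature-free position to anchor the origin"
    )


def build_site_registry(reference: AnnotatedGenome) -> IntronSiteRegistry:
    """One :class:`IntronSite` per reference intron, ordered 5'→3' per gene.

    Each site carries a single founding :class:`TypeExemplar` taken from the
    reference intron's own sequence, labelled ``"<ordinal>-1"``.
    """
    reference = _unwrap_origin(reference)
    reg = IntronSiteRegistry()
    gene_names_in_order = [f.name for f in reference.genes()]
    for gene_name in gene_names_in_order:
        introns = reference.introns_of(gene_name)
        if not introns:
            continue
        gene = reference.get_gene(gene_name)
        located = sorted(
            ((intron_spliced_position(gene, it), it) for it in introns),
            key=lambda t: t[0],
        )
        last = -1
        for ordinal, (pos, it) in enumerate(located, start=1):
            if pos <= last:
                raise GenomeValidationError(
                    f"{gene_name}: introns with non-increasing spliced "
                    f"positions ({pos} after {last})"
                )
            last = pos
            label = f"{ordinal}-1"
            site = IntronSite(
                gene=gene_name,
                ordinal=ordinal,
                spliced_pos=pos,
                intron_class=it.qualifiers.get("intron_class", "unknown"),
            )
            site.known_types[label] = TypeExemplar(
                type_label=label, exemplar_seq=feature_sequence(reference, it)
            )
            reg.add(site)
    return reg


def classify_intron_type(
    site: IntronSite,
    seq: str,
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    register_new: bool = True,
) -> tuple[str, str | None]:
    """Assign ``seq`` to a known type at ``site`` or register a new one.

    Identity is global-alignment identity (edit distance over the longer
    sequence length).  Ties between exemplars break toward the
    lexicographically smaller type label.  Within a type, the subtype label
    is the joint state at the type's declared variant columns: all reference
    states → ``"A"``, all alternate → ``"B"``, otherwise the per-column
    pattern; ``None`` when the type declares no variant columns.
    """
    if not seq:
        raise ValueError("cannot classify an empty intron sequence")
    best_label, best_ident = None, -1.0
    for label in sorted(site.known_types):
        ex = site.known_types[label]
        d = edlib.align(seq, ex.exemplar_seq, mode="NW", task="distance")["editDistance"]
        ident = 1.0 - d / max(len(seq), len(ex.exemplar_seq))
        if ident > best_ident:
            best_label, best_ident = label, ident
    if best_label is not None and best_ident >= id_threshold:
        ex = site.known_types[best_label]
        return best_label, _call_subtype(seq, ex)
    # novel type
    n = len(site.known_types) + 1
    label = f"{site.ordinal}-{n}"
    while label in site.known_types:
        n += 1
        label = f"{site.ordinal}-{n}"
    if register_new:
        site.known_types[label] = TypeExemplar(type_label=label, exemplar_seq=seq)
    return label, None


def _cigar_ops(cigar: str):
    for m in re.finditer(r"(\d+)([=XIDM])", cigar):
        yield int(m.group(1)), m.group(2)


def _target_to_query_map(query: str, target: str) -> list[int]:
    """``t2q[t]`` = query coordinate aligned at target boundary ``t``."""
    res = edlib.align(query, target, mode="NW", task="path")
    t2q = [0] * (len(target) + 1)
    q = t = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op in "=XM":
            for _ in range(n):
                q += 1
                t += 1
                t2q[t] = q
        elif op == "I":  # query-only bases; boundary keeps pre-insertion q
            q += n
            if t < len(target):
                pass
            t2q[t] = max(t2q[t], t2q[t])
        elif op == "D":
            for _ in range(n):
                t += 1
                t2q[t] = q
    t2q[len(target)] = len(query)
    return t2q


def _call_subtype(seq: str, ex: TypeExemplar, window: int = 6) -> str | None:
    """Per-column subtype call, robust to gap-placement ambiguity.

    For each declared variant column the query segment aligned to a small
    window around it is compared (by edit distance) against the window
    realized with the reference state and with the alternate state."""
    if not ex.subtype_variants:
        return None
    t2q = _target_to_query_map(seq, ex.exemplar_seq)
    t = ex.exemplar_seq
    calls = []
    for pos, ref_state, alt_state in ex.subtype_variants:
        lo = max(0, pos - window)
        hi = min(len(t), pos + len(ref_state) + window)
        obs = seq[t2q[lo] : t2q[hi]]
        cand_ref = t[lo:hi]
        cand_alt = t[lo:pos] + alt_state + t[pos + len(ref_state) : hi]
        d_ref = edlib.align(obs, cand_ref, mode="NW", task="distance")["editDistance"]
        d_alt = edlib.align(obs, cand_alt, mode="NW", task="distance")["editDistance"]
        if d_ref < d_alt:
            calls.append("A")
        elif d_alt < d_ref:
            calls.append("B")
        else:
            calls.append("?")
    if all(c == "A" for c in calls):
        return "A"
    if all(c == "B" for c in calls):
        return "B"
    return "".join(calls)


def _affine_aligner() -> Align.PairwiseAligner:
    # affine gaps keep foreign inserts contiguous instead of letting an
    # edit-distance path scatter them over cheap spurious matches
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -0.2
    return aligner


def detect_intron_anomalies(
    obs_seq: str,
    exemplar: TypeExemplar,
    insert_min: int = DEFAULT_INSERT_MIN,
    cover_min: float = DEFAULT_COVER_MIN,
) -> tuple[list[tuple[int, int]], bool]:
    """Insertions and degeneracy of an intron copy relative to its exemplar.

    Returns ``(inserts, degenerate)``: query-only runs of at least
    ``insert_min`` nt as ``(exemplar_offset, length)`` pairs, and a flag set
    when less than ``cover_min`` of the exemplar aligns to the query.
    """
    target = exemplar.exemplar_seq
    aln = _affine_aligner().align(obs_seq, target)[0]
    q_blocks, t_blocks = aln.aligned
    inserts: list[tuple[int, int]] = []
    aligned_target = 0
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        aligned_target += te - ts
        if prev_q is not None:
            q_gap = qs - prev_q
            t_gap = ts - prev_t
            if q_gap - t_gap >= insert_min:
                inserts.append((prev_t, q_gap - t_gap))
        prev_q, prev_t = qe, te
    coverage = aligned_target / max(1, len(target))
    return [(int(t0), int(ln)) for t0, ln in inserts], bool(coverage < cover_min)


def map_introns(
    query: AnnotatedGenome,
    registry: IntronSiteRegistry,
    tol: int = DEFAULT_TOL,
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    insert_min: int = DEFAULT_INSERT_MIN,
    cover_min: float = DEFAULT_COVER_MIN,
    classify: bool = True,
) -> list[IntronObservation]:
    """Map every intron of ``query`` onto the registry's homologous sites.

    Each query intron is assigned to the nearest registry site of its host
    gene within ``tol`` nt in the query's own spliced coordinates; introns
    with no match register a novel site.  Every registry site yields exactly
    one observation per strain (``present=False`` when empty).  Two query
    introns mapping to one site raise an error: a single site cannot hold
    two introns, so this indicates an annotation fault.
    """
    query = _unwrap_origin(query)
    assigned: dict[tuple[str, int], Feature] = {}
    obs_by_site: dict[tuple[str, int], IntronObservation] = {}
    novel_keys: set[tuple[str, int]] = set()

    query_genes = {f.name for f in query.genes()}
    for gene_name in sorted({f.qualifiers.get("host_gene", "") for f in query.features if f.kind == "intron"}):
        if not gene_name:
            continue
        if gene_name not in query_genes:
            raise GenomeValidationError(
                f"{query.strain_id}: intron host gene {gene_name!r} not annotated"
            )
        gene = query.get_gene(gene_name)
        for it in query.introns_of(gene_name):
            pos = intron_spliced_position(gene, it)
            site = registry.match(gene_name, pos, tol)
            is_novel = site is None
            if is_novel:
                site = registry.augment(
                    gene_name, pos, tol, it.qualifiers.get("intron_class", "unknown")
                )
                novel_keys.add(site.key)
            if site.key in assigned:
                other = assigned[site.key]
                raise GenomeValidationError(
                    f"{query.strain_id}: introns {other.name!r} at {other.span()} "
                    f"and {it.name!r} at {it.span()} both map to site {site.key}"
                )
            assigned[site.key] = it
            seq = feature_sequence(query, it)
            ob = IntronObservation(
                strain_id=query.strain_id,
                site=site.key,
                present=True,
                length=len(seq),
                novel_site=site.key in novel_keys or site.novel,
            )
            if classify:
                ob.type_label, ob.subtype_label = classify_intron_type(
                    site, seq, id_threshold=id_threshold
                )
                ex = site.known_types[ob.type_label]
                if ex.exemplar_seq != seq:
                    ob.inserts, ob.degenerate = detect_intron_anomalies(
                        seq, ex, insert_min=insert_min, cover_min=cover_min
                    )
            obs_by_site[site.key] = ob

    out: list[IntronObservation] = []
    for site in registry.sites:
        if site.key in obs_by_site:
            out.append(obs_by_site[site.key])
        else:
            out.append(
                IntronObservation(
                    strain_id=query.strain_id,
                    site=site.key,
                    present=False,
                    novel_site=site.novel,
                )
            )
    return out


# ---------------------------------------------------------------------------
# state matrix
# ---------------------------------------------------------------------------

ABSENT = "0"


def observation_state(ob: IntronObservation) -> str:
    """Categorical cell state: ``0`` or ``type[:subtype][+insN...]``."""
    if not ob.present:
        return ABSENT
    state = ob.type_label or "present"
    if ob.subtype_label:
        state += f":{ob.subtype_label}"
    for _, length in ob.inserts:
        state += f"+ins{length}"
    if ob.degenerate:
        state += "~deg"
    return state


def observations_to_matrix(
    all_obs: dict[str, list[IntronObservation]],
    registry: IntronSiteRegistry,
    include_novel: bool = True,
) -> pd.DataFrame:
    """Strains × sites categorical matrix; absence is a state, never NaN."""
    sites = [s for s in registry.sites if include_novel or not s.novel]
    cols = [f"{s.gene}.{s.ordinal}" for s in sites]
    keys = {s.key: f"{s.gene}.{s.ordinal}" for s in sites}
    data = {}
    for strain, obs in all_obs.items():
        row = {c: ABSENT for c in cols}
        for ob in obs:
            if ob.site in keys:
                row[keys[ob.site]] = observation_state(ob)
        data[strain] = row
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    df.index.name = "strain_id"
    return df


def write_state_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_state_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)
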