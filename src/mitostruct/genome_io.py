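"""Reading, writing and normalizing annotated circular mitochondrial genomes.

This module defines the in-memory representation every other stage of the
package consumes: an :class:`AnnotatedGenome` holding a circular nucleotide
sequence, a flat list of :class:`Feature` records (genes, tRNAs, rRNAs,
introns, plasmid-derived *dpo* fragments) and per-strain metadata.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open, on the forward strand.
GenBank I/O converts to and from the 1-based inclusive GenBank dialect.
Feature segments are stored in 5'→3' order *in gene orientation*: ascending
for ``+`` features, descending for ``-`` features.  A feature that crosses
the origin of the circular sequence is represented with two segments.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "StrainMeta",
    "AnnotatedGenome",
    "GenomeStats",
    "GenomeParseError",
    "GenomeValidationError",
    "FEATURE_KINDS",
    "read_annotated_genome",
    "write_annotated_genome",
    "read_genbank",
    "write_genbank",
    "read_fasta_table",
    "write_fasta_table",
    "read_metadata_table",
    "write_metadata_table",
    "normalize_orientation",
    "rotate_genome",
    "reverse_complement_genome",
    "compute_genome_stats",
    "spliced_sequence",
    "feature_sequence",
]

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "intron", "dpo", "other")

_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeParseError(ValueError):
    """Raised when an input record cannot be parsed in the named format."""


class GenomeValidationError(ValueError):
    """Raised when a parsed record violates a structural invariant."""


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """A located annotation on the forward strand of a genome.

    ``segments`` is an ordered list of ``(start, end)`` half-open intervals
    in 5'→3' order of the feature itself; for a ``-`` strand feature the
    intervals therefore appear in descending coordinate order.
    """

    name: str
    kind: str
    strand: str
    segments: list[tuple[int, int]]
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise GenomeValidationError(
                f"feature {self.name!r}: unknown kind {self.kind!r}"
            )
        if self.strand not in "+-":
            raise GenomeValidationError(
                f"feature {self.name!r}: strand must be '+' or '-'"
            )
        self.segments = [(int(s), int(e)) for s, e in self.segments]
        for s, e in self.segments:
            if e <= s:
                raise GenomeValidationError(
                    f"feature {self.name!r}: empty or inverted segment [{s}, {e})"
                )

    @property
    def start(self) -> int:
        """Smallest forward-strand coordinate covered."""
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        """Largest forward-strand coordinate covered (exclusive)."""
        return max(e for _, e in self.segments)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class StrainMeta:
    """Per-strain metadata: clade assignment, variety, origin, cultivar status."""

    clade: str = "unknown"
    variety: str = "unknown"
    origin: str = "unknown"
    cultivar_status: str = "unknown"

    VARIETIES = ("bisporus", "burnettii", "eurotetrasporus", "outgroup", "unknown")
    CULTIVAR_STATUSES = ("cultivar", "cultivar-like", "wild", "unknown")

    def __post_init__(self) -> None:
        if self.variety not in self.VARIETIES:
            raise GenomeValidationError(f"unknown variety {self.variety!r}")
        if self.cultivar_status not in self.CULTIVAR_STATUSES:
            raise GenomeValidationError(
                f"unknown cultivar_status {self.cultivar_status!r}"
            )


@dataclass
class AnnotatedGenome:
    """A circular mitogenome: sequence, features, and strain metadata."""

    strain_id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = True
    metadata: StrainMeta = field(default_factory=StrainMeta)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GenomeValidationError(f"{self.strain_id}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise GenomeParseError(
                f"{self.strain_id}: ambiguity codes other than N are not "
                f"supported: {sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            if f.start < 0 or f.end > n:
                raise GenomeValidationError(
                    f"{self.strain_id}: feature {f.name!r} outside [0, {n})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def genes(self) -> list[Feature]:
        """Gene-level features (CDS and rRNAs) that can host introns."""
        return self.features_of_kind("CDS", "rRNA")

    def get_gene(self, name: str) -> Feature:
        hits = [f for f in self.genes() if f.name == name]
        if len(hits) != 1:
            available = sorted({f.name for f in self.genes()})
            raise GenomeValidationError(
                f"{self.strain_id}: gene {name!r} found {len(hits)} times; "
                f"available genes: {available}"
            )
        return hits[0]

    def introns_of(self, gene_name: str) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.kind == "intron" and f.qualifiers.get("host_gene") == gene_name
        ]


@dataclass(frozen=True)
class GenomeStats:
    """Whole-genome composition statistics on the normalized forward strand."""

    length: int
    at_content: float
    gc_skew: float
    n_count: int


# ---------------------------------------------------------------------------
# composition statistics
# ---------------------------------------------------------------------------


def compute_genome_stats(g: AnnotatedGenome) -> GenomeStats:
    """AT content, GC skew ((G−C)/(G+C)) and N count of the forward strand.

    N bases are excluded from the fractional statistics but reported in
    ``n_count``.  A sequence with no G or C bases yields a GC skew of 0 with
    a warning.
    """
    s = g.sequence
    a, c, gg, t, n = (s.count(b) for b in "ACGTN")
    non_n = a + c + gg + t
    if non_n == 0:
        raise GenomeValidationError(f"{g.strain_id}: sequence is all N")
    at = (a + t) / non_n
    if gg + c == 0:
        warnings.warn(f"{g.strain_id}: no G/C bases; GC skew reported as 0")
        skew = 0.0
    else:
        skew = (gg - c) / (gg + c)
    return GenomeStats(length=len(s), at_content=at, gc_skew=skew, n_count=n)


# ---------------------------------------------------------------------------
# rotation / strand normalization
# ---------------------------------------------------------------------------


def rotate_genome(g: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate a circular genome so that current position ``offset`` becomes 0.

    Features whose segments cross the new origin are split into two segments
    so every stored interval stays inside ``[0, length)``.
    """
    n = len(g.sequence)
    offset %= n
    if offset == 0:
        return replace(g, features=[replace(f) for f in g.features])
    seq = g.sequence[offset:] + g.sequence[:offset]
    feats = []
    for f in g.features:
        segs: list[tuple[int, int]] = []
        for s, e in f.segments:
            ns = (s - offset) % n
            if ns + (e - s) <= n:
                segs.append((ns, ns + (e - s)))
            else:  # wraps the new origin: split
                first = (ns, n)
                second = (0, (e - s) - (n - ns))
                if f.strand == "+":
                    segs.extend([first, second])
                else:
                    # 5'→3' for '-' runs right-to-left through the split
                    segs.extend([second, first])
        feats.append(replace(f, segments=segs))
    return replace(g, sequence=seq, features=feats)


def reverse_complement_genome(g: AnnotatedGenome) -> AnnotatedGenome:
    """Reverse-complement the genome, remapping all features consistently."""
    n = len(g.sequence)
    seq = _revcomp(g.sequence)
    feats = []
    for f in g.features:
        segs = [(n - e, n - s) for s, e in f.segments]
        feats.append(
            replace(f, strand="-" if f.strand == "+" else "+", segments=segs)
        )
    return replace(g, sequence=seq, features=feats)


def normalize_orientation(
    g: AnnotatedGenome, anchor_gene: str = "cox1"
) -> AnnotatedGenome:
    """Rotate/flip the genome so ``anchor_gene`` starts at 0 on ``+``.

    The anchor must be annotated exactly once.  If it lies on the reverse
    strand the whole genome is reverse-complemented first, so that the
    normalized representation is unique for every rotation and strand of
    the same circular molecule.
    """
    anchor = g.get_gene(anchor_gene)
    if anchor.strand == "-":
        g = reverse_complement_genome(g)
        anchor = g.get_gene(anchor_gene)
    # 5' end of a '+' feature is the first segment's start
    return rotate_genome(g, anchor.segments[0][0])


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------


def _segment_seq(g: AnnotatedGenome, seg: tuple[int, int], strand: str) -> str:
    s = g.sequence[seg[0] : seg[1]]
    return _revcomp(s) if strand == "-" else s


def feature_sequence(g: AnnotatedGenome, f: Feature) -> str:
    """The feature's nucleotide sequence, 5'→3' in gene orientation."""
    return "".join(_segment_seq(g, seg, f.strand) for seg in f.segments)


def spliced_sequence(g: AnnotatedGenome, gene: Feature) -> str:
    """Concatenated exonic sequence of a gene (its segments, spliced)."""
    return feature_sequence(g, gene)


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_KIND_TO_GB = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "intron": "intron",
    "dpo": "misc_feature",
    "other": "misc_feature",
}


def _feature_to_biopython(f: Feature) -> SeqFeature:
    strand = 1 if f.strand == "+" else -1
    locs = [SimpleLocation(s, e, strand=strand) for s, e in f.segments]
    if f.strand == "-":
        # GenBank complement(join(...)) lists parts in ascending order
        locs = locs[::-1]
    loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    quals = {k: [v] for k, v in f.qualifiers.items()}
    quals["gene"] = [f.name]
    quals["mitostruct_kind"] = [f.kind]
    return SeqFeature(location=loc, type=_KIND_TO_GB[f.kind], qualifiers=quals)


def _q1(quals: dict, key: str) -> str | None:
    v = quals.get(key)
    if not v:
        return None
    return v[0] if isinstance(v, list) else str(v)


def _feature_from_biopython(sf: SeqFeature) -> Feature | None:
    name = (
        _q1(sf.qualifiers, "gene")
        or _q1(sf.qualifiers, "label")
        or _q1(sf.qualifiers, "product")
        or _q1(sf.qualifiers, "locus_tag")
    )
    if name is None:
        name = sf.type
    kind = _q1(sf.qualifiers, "mitostruct_kind")
    if kind is None:
        if sf.type in ("CDS", "rRNA", "tRNA", "intron"):
            kind = sf.type
        elif name.lower().startswith("dpo"):
            kind = "dpo"
        elif sf.type in ("gene", "source"):
            return None  # redundant with CDS/rRNA records
        else:
            kind = "other"
    strand = "-" if sf.location.strand == -1 else "+"
    parts = sorted(
        ((int(p.start), int(p.end)) for p in sf.location.parts), key=lambda t: t[0]
    )
    if strand == "-":
        parts = parts[::-1]
    quals = {
        k: _q1(sf.qualifiers, k)
        for k in sf.qualifiers
        if k not in ("gene", "mitostruct_kind", "translation")
    }
    return Feature(name=name, kind=kind, strand=strand, segments=parts, qualifiers=quals)


def _validate_introns(g: AnnotatedGenome) -> None:
    gene_names = {f.name for f in g.genes()}
    for f in g.features:
        if f.kind != "intron":
            continue
        host = f.qualifiers.get("host_gene")
        if host is None or host not in gene_names:
            raise GenomeValidationError(
                f"{g.strain_id}: intron {f.name!r} at {f.span()} has no "
                f"resolvable host gene (host_gene={host!r})"
            )


def read_genbank(path: str | Path, metadata: StrainMeta | None = None) -> AnnotatedGenome:
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises bare ValueError on bad records
        raise GenomeParseError(f"{path}: not a valid GenBank record: {exc}") from exc
    feats = []
    for sf in record.features:
        f = _feature_from_biopython(sf)
        if f is not None:
            feats.append(f)
    g = AnnotatedGenome(
        strain_id=record.id or record.name,
        sequence=str(record.seq),
        features=feats,
        circular=record.annotations.get("topology", "circular") == "circular",
        metadata=metadata or StrainMeta(),
    )
    _validate_introns(g)
    return g


def write_genbank(g: AnnotatedGenome, path: str | Path) -> None:
    record = SeqRecord(
        Seq(g.sequence),
        id=g.strain_id,
        name=g.strain_id[:16].replace(" ", "_"),
        description=f"{g.strain_id} mitochondrial genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if g.circular else "linear"
    record.features = [_feature_to_biopython(f) for f in g.features]
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + annotation-table I/O
# ---------------------------------------------------------------------------

_TABLE_COLS = ["strain_id", "feature_name", "kind", "strand", "segments"]


def _segments_to_text(segs: Iterable[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in segs)


def _segments_from_text(text: str) -> list[tuple[int, int]]:
    segs = []
    for part in text.split(";"):
        s, _, e = part.partition("-")
        segs.append((int(s), int(e)))
    return segs


def read_fasta_table(
    fasta_path: str | Path,
    table_path: str | Path,
    metadata: StrainMeta | None = None,
) -> AnnotatedGenome:
    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except Exception as exc:
        raise GenomeParseError(f"{fasta_path}: not a valid FASTA record: {exc}") from exc
    feats: list[Feature] = []
    with open(table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TABLE_COLS) - set(reader.fieldnames or [])
        if missing:
            raise GenomeParseError(
                f"{table_path}: missing columns {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=2):
            if row["strain_id"] != record.id:
                continue
            try:
                quals = {}
                for item in (row.get("qualifiers") or "").split("|"):
                    if item:
                        k, _, v = item.partition("=")
                        quals[k] = v
                feats.append(
                    Feature(
                        name=row["feature_name"],
                        kind=row["kind"],
                        strand=row["strand"],
                        segments=_segments_from_text(row["segments"]),
                        qualifiers=quals,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise GenomeParseError(f"{table_path} line {i}: {exc}") from exc
    g = AnnotatedGenome(
        strain_id=record.id,
        sequence=str(record.seq),
        features=feats,
        metadata=metadata or StrainMeta(),
    )
    _validate_introns(g)
    return g


def write_fasta_table(
    g: AnnotatedGenome, fasta_path: str | Path, table_path: str | Path
) -> None:
    record = SeqRecord(Seq(g.sequence), id=g.strain_id, description="")
    SeqIO.write([record], str(fasta_path), "fasta")
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLS + ["qualifiers"])
        for f in g.features:
            writer.writerow(
                [
                    g.strain_id,
                    f.name,
                    f.kind,
                    f.strand,
                    _segments_to_text(f.segments),
                    "|".join(f"{k}={v}" for k, v in sorted(f.qualifiers.items())),
                ]
            )


def read_annotated_genome(
    path: str | Path,
    format: str = "genbank",
    table: str | Path | None = None,
    metadata: StrainMeta | None = None,
) -> AnnotatedGenome:
    """Read an annotated genome from GenBank or FASTA + annotation table."""
    if format == "genbank":
        return read_genbank(path, metadata=metadata)
    if format == "fasta+table":
        if table is None:
            raise GenomeParseError("fasta+table format requires a table path")
        return read_fasta_table(path, table, metadata=metadata)
    raise GenomeParseError(f"unknown format {format!r}")


def write_annotated_genome(
    g: AnnotatedGenome,
    path: str | Path,
    format: str = "genbank",
    table: str | Path | None = None,
) -> None:
    if format == "genbank":
        write_genbank(g, path)
    elif format == "fasta+table":
        if table is None:
            raise GenomeParseError("fasta+table format requires a table path")
        write_fasta_table(g, path, table)
    else:
        raise GenomeParseError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# strain metadata tables
# ---------------------------------------------------------------------------

_META_COLS = ["strain_id", "clade", "variety", "origin", "cultivar_status"]


def read_metadata_table(path: str | Path) -> dict[str, StrainMeta]:
    metas: dict[str, StrainMeta] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sid = row["strain_id"]
            if sid in metas:
                raise GenomeValidationError(f"{path}: duplicate strain_id {sid!r}")
            metas[sid] = StrainMeta(
                clade=row.get("clade") or "unknown",
                variety=row.get("variety") or "unknown",
                origin=row.get("origin") or "unknown",
                cultivar_status=row.get("cultivar_status") or "unknown",
            )
    return metas


def write_metadata_table(metas: dict[str, StrainMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_META_COLS)
        for sid in sorted(metas):
            m = metas[sid]
            writer.writerow([sid, m.clade, m.variety, m.origin, m.cultivar_status])
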