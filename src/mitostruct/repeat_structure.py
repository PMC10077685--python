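"""Inverted-repeat (IRS) detection and MIR orientation calling.

Fungal mitogenomes in the *Agaricus* group carry a pair of long inverted
repeats (each composed of ~8 tRNA genes) flanking an invertible segment —
the MIR ("middle of the two inverted repeats") — that contains nad2, nad3,
rrnL and rps3.  The orientation of the MIR differs between clades, so
calling it per strain is a structural character.

Detection is seed-and-extend: exact k-mer matches between the forward
strand and its reverse complement are chained on anti-diagonals and the
resulting candidate pair is polished by greedy X-drop extension plus a
global alignment to score identity.  Orientation is called from the strand
of a marker gene (rps3 by default) relative to the normalization anchor
(cox1), so the call is self-contained per genome.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import edlib

from .genome_io import AnnotatedGenome, Feature, _revcomp

__all__ = ["RepeatPair", "MIRReport", "detect_inverted_repeats", "call_mir"]

DEFAULT_MIN_LEN = 500
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MARKERS = ("nad2", "nad3", "rrnL", "rps3")
SEED_K = 21


@dataclass(frozen=True)
class RepeatPair:
    """Two segments whose sequences are reverse complements of each other."""

    copy_a: tuple[int, int]
    copy_b: tuple[int, int]
    identity: float
    length: int

    @property
    def score(self) -> float:
        return self.length * self.identity


@dataclass
class MIRReport:
    """Orientation call for the segment between the two IRS copies."""

    segment: tuple[int, int]
    orientation: str  # forward | reverse | duplicated_both
    markers_found: list[str]
    evidence: dict[str, str]  # marker gene -> strand vote


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences (matches / columns)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    cols = max(len(a), len(b))  # lower bound on alignment columns
    return max(0.0, 1.0 - res["editDistance"] / cols)


def _xdrop_extend(
    s: str, a_end: int, b_start: int, direction: int, xdrop: int = 15,
    min_gain: int = 3,
) -> int:
    """Extend an inverted match outward; returns number of extra bases kept.

    ``direction`` +1 extends copy_a rightwards / copy_b leftwards (inner
    boundary); -1 extends copy_a leftwards / copy_b rightwards (outer).
    Scoring +1 match / -2 mismatch, stop when score drops ``xdrop`` below
    its running maximum.
    """
    n = len(s)
    best, score, best_i = 0, 0, 0
    i = 1
    while True:
        if direction > 0:
            pa, pb = a_end + i - 1, b_start - i
        else:
            pa, pb = a_end - i, b_start + i - 1  # here a_end=a_start, b_start=b_end
        if pa < 0 or pb < 0 or pa >= n or pb >= n or pa >= pb:
            break
        match = s[pa] == _revcomp(s[pb])
        score += 1 if match else -2
        if score > best:
            best, best_i = score, i
        if best - score > xdrop:
            break
        i += 1
    # a couple of chance matches in random flanking sequence must not move
    # the boundary; demand a clear net gain before extending at all
    return best_i if best >= min_gain else 0


def detect_inverted_repeats(
    g: AnnotatedGenome,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = SEED_K,
    band: int = 200,
) -> list[RepeatPair]:
    """Find maximal non-nested inverted repeat pairs in a circular genome.

    Pairs are ranked by ``length * identity`` (ties broken by smaller
    ``copy_a`` start) and nested/overlapping duplicates are suppressed.
    The search runs on the doubled sequence so repeats spanning the origin
    of the circular molecule are found; coordinates are reported mod L.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    L = len(g.sequence)
    s = g.sequence + g.sequence if g.circular else g.sequence
    n = len(s)

    # exact k-mer seeds between s and revcomp(s): position i matches position
    # j (i < j) when s[i:i+k] == revcomp(s[j:j+k])
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        index[s[i : i + k]].append(i)
    # anti-diagonal chaining: for a perfect inverted repeat, i + j is constant
    chains: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for j in range(n - k + 1):
        rc = _revcomp(s[j : j + k])
        for i in index.get(rc, ()):
            if i + k <= j and j - i < L:  # non-overlapping copies, span < one turn
                c = (i + j) // band
                chains[c].append((i, j))

    candidates: list[tuple[int, int, int, int]] = []
    merged: dict[int, list[tuple[int, int]]] = {}
    for c, seeds in chains.items():
        bucket = merged.setdefault(c // 1, [])
        bucket.extend(seeds)
    # merge adjacent bands
    seen_bands = sorted(merged)
    groups: list[list[tuple[int, int]]] = []
    prev_band = None
    for c in seen_bands:
        if prev_band is not None and c - prev_band <= 1:
            groups[-1].extend(merged[c])
        else:
            groups.append(list(merged[c]))
        prev_band = c
    for seeds in groups:
        is_ = [i for i, _ in seeds]
        js = [j for _, j in seeds]
        a0, a1 = min(is_), max(is_) + k
        b0, b1 = min(js), max(js) + k
        if a1 > b0:  # copies overlap (palindrome core); clip
            mid = (a1 + b0) // 2
            a1, b0 = mid, mid
        # polish boundaries by X-drop extension
        inner = _xdrop_extend(s, a1, b0, +1)
        outer = _xdrop_extend(s, a0, b1, -1)
        a0, b1 = a0 - outer, b1 + outer
        a1, b0 = a1 + inner, b0 - inner
        if a1 > b0:
            mid = (a1 + b0) // 2
            a1, b0 = mid, mid
        candidates.append((a0, a1, b0, b1))

    pairs: list[RepeatPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for a0, a1, b0, b1 in candidates:
        length = min(a1 - a0, b1 - b0)
        if length < min_len:
            continue
        ident = _alignment_identity(s[a0:a1], _revcomp(s[b0:b1]))
        if ident < min_identity:
            continue
        key = (a0 % L, a1 - a0, b0 % L, b1 - b0)
        # canonicalize: copy_a is the copy with the smaller (mod L) start
        ca = (a0 % L, a0 % L + (a1 - a0))
        cb = (b0 % L, b0 % L + (b1 - b0))
        if cb[0] < ca[0]:
            ca, cb = cb, ca
        key = (ca[0], ca[1], cb[0], cb[1])
        if key in seen:
            continue
        seen.add(key)
        pairs.append(RepeatPair(copy_a=ca, copy_b=cb, identity=ident, length=length))

    # suppress nested / duplicate pairs: keep best-scoring, drop any pair
    # whose copies substantially overlap an already-kept pair's copies
    pairs.sort(key=lambda p: (-p.score, p.copy_a[0]))
    kept: list[RepeatPair] = []

    def _overlap(x: tuple[int, int], y: tuple[int, int]) -> int:
        return max(0, min(x[1], y[1]) - max(x[0], y[0]))

    for p in pairs:
        dup = False
        for q in kept:
            if (
                _overlap(p.copy_a, q.copy_a) > 0.5 * p.length
                and _overlap(p.copy_b, q.copy_b) > 0.5 * p.length
            ):
                dup = True
                break
        if not dup:
            kept.append(p)
    if len(kept) > 5:
        warnings.warn(
            f"{g.strain_id}: {len(kept)} repeat pairs pass thresholds; "
            "genome may be repeat-rich"
        )
    return kept


# ---------------------------------------------------------------------------
# MIR orientation
# ---------------------------------------------------------------------------


def _in_arc(pos: int, arc: tuple[int, int], L: int) -> bool:
    """Is position ``pos`` inside circular arc [start, end)?"""
    start, end = arc
    if start <= end:
        return start <= pos < end
    return pos >= start or pos < end


def _arc_len(arc: tuple[int, int], L: int) -> int:
    start, end = arc
    return (end - start) % L if (end - start) % L else (L if start == end else 0)


def call_mir(
    g: AnnotatedGenome,
    repeats: list[RepeatPair],
    marker_genes: tuple[str, ...] = DEFAULT_MARKERS,
    anchor_gene: str = "cox1",
    orientation_marker: str = "rps3",
) -> MIRReport:
    """Call the orientation of the segment between the dominant IRS pair.

    The MIR segment is the arc strictly between the two repeat copies that
    contains the marker genes (ties broken toward the shorter arc).  The
    orientation is the strand of ``orientation_marker`` relative to the
    strand of ``anchor_gene``: same strand → forward, opposite → reverse.
    If two MIR-homolog copies are annotated in opposite orientations the
    call is ``duplicated_both``.
    """
    if not repeats:
        raise ValueError(f"{g.strain_id}: no IRS detected")
    L = len(g.sequence)
    dominant = max(repeats, key=lambda p: (p.length, -p.copy_a[0]))
    a, b = dominant.copy_a, dominant.copy_b
    arc1 = (a[1] % L, b[0] % L)  # between copy_a end and copy_b start
    arc2 = (b[1] % L, a[0] % L)

    def _markers_in(arc: tuple[int, int]) -> list[Feature]:
        found = []
        for f in g.features:
            if f.name in marker_genes and f.kind in ("CDS", "rRNA"):
                mid = (f.start + f.end) // 2
                if _in_arc(mid % L, arc, L):
                    found.append(f)
        return found

    m1, m2 = _markers_in(arc1), _markers_in(arc2)
    if len(m1) > len(m2):
        segment, markers = arc1, m1
    elif len(m2) > len(m1):
        segment, markers = arc2, m2
    elif _arc_len(arc1, L) <= _arc_len(arc2, L):
        segment, markers = arc1, m1
    else:
        segment, markers = arc2, m2

    # duplicated_both: a marker gene appears on both strands (two MIR
    # homologs in opposite orientations).  Checked before the in-segment
    # marker requirement because the duplicate pair itself can outrank the
    # IRS as the dominant repeat.
    by_name: dict[str, set[str]] = defaultdict(set)
    for f in g.features:
        if f.name in marker_genes and f.kind in ("CDS", "rRNA"):
            by_name[f.name].add(f.strand)
    duplicated = any(len(strands) == 2 for strands in by_name.values())

    if not markers and not duplicated:
        raise ValueError(
            f"{g.strain_id}: no marker gene inside candidate MIR segment "
            f"{segment} (markers sought: {list(marker_genes)})"
        )

    anchor = g.get_gene(anchor_gene)
    evidence = {f.name: f.strand for f in markers}

    if duplicated:
        orientation = "duplicated_both"
        if not markers:
            markers = [
                f for f in g.features
                if f.name in marker_genes and f.kind in ("CDS", "rRNA")
            ]
    else:
        om = [f for f in markers if f.name == orientation_marker]
        if not om:
            om = markers  # fall back to majority vote of present markers
        votes = [f.strand for f in om]
        strand = max(set(votes), key=votes.count)
        orientation = "forward" if strand == anchor.strand else "reverse"

    return MIRReport(
        segment=segment,
        orientation=orientation,
        markers_found=sorted({f.name for f in markers}),
        evidence=evidence,
    )
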