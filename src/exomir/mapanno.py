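"""Alignment to hairpin/genome references, multi-mapper weighting, and
hierarchical ncRNA annotation.

Alignment is exact-substring search (with an optional Hamming neighborhood of
up to 2 mismatches via pigeonhole seeding, no indels), reporting all hits in
the best stratum — the behaviour of a short-read aligner run in ``-v`` mode
at desk scale, bit-reproducible. Reads hitting k locations are weighted 1/k.

A hit is called miRNA when its interval lies inside a mature window extended
by ``mature_extension`` (default 2 nt) on both sides, accommodating imprecise
precursor processing; otherwise it takes the class of its containing feature
under the fixed priority miRNA > tRNA > rRNA > snRNA > repeat > other_ncRNA >
unannotated.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .reference import ReferenceBundle
from .readprep import ReadRecord

_COMP = str.maketrans("ACGTN", "TGCAN")

CATEGORY_PRIORITY = ("miRNA", "tRNA", "rRNA", "snRNA", "repeat", "other_ncRNA", "unannotated")
_CLS_TO_CATEGORY = {"tRNA": "tRNA", "rRNA": "rRNA", "snRNA": "snRNA",
                    "repeat": "repeat", "other": "other_ncRNA",
                    # hairpin-contained but outside any mature window: still an
                    # annotated ncRNA locus (precursor fragment)
                    "miRNA_hairpin": "other_ncRNA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    target_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    weight: float = 1.0


@dataclass(frozen=True)
class AnnotatedRead:
    read_id: str
    category: str
    mature_id: str | None
    weight: float
    target_id: str | None = None
    start: int | None = None
    end: int | None = None


def _occurrences(read: str, ref: str, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) placements of ``read`` in ``ref`` with at most
    ``max_mm`` substitutions (no indels)."""
    out = []
    if max_mm == 0:
        i = ref.find(read)
        while i != -1:
            out.append((i, 0))
            i = ref.find(read, i + 1)
        return out
    # pigeonhole: one of max_mm+1 segments must match exactly
    n = len(read)
    k = max_mm + 1
    bounds = [round(j * n / k) for j in range(k + 1)]
    cands: set[int] = set()
    for j in range(k):
        seg = read[bounds[j]:bounds[j + 1]]
        i = ref.find(seg)
        while i != -1:
            s = i - bounds[j]
            if 0 <= s <= len(ref) - n:
                cands.add(s)
            i = ref.find(seg, i + 1)
    for s in sorted(cands):
        mm = sum(a != b for a, b in zip(read, ref[s:s + n]))
        if mm <= max_mm:
            out.append((s, mm))
    return out


def align(
    reads: list[ReadRecord] | list[tuple[str, str]] | dict[str, str],
    references: dict[str, str],
    max_mismatches: int = 0,
    search_revcomp: bool = False,
) -> dict[str, list[AlignmentHit]]:
    """Map each read against all references; keep the best (fewest-mismatch)
    stratum per read. Returns read_id -> hits (empty list if unmapped)."""
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    if not references or any(not s for s in references.values()):
        raise ValueError("references must be non-empty sequences")
    items: list[tuple[str, str]]
    if isinstance(reads, dict):
        items = list(reads.items())
    else:
        items = [(r.read_id, r.sequence) if isinstance(r, ReadRecord) else (r[0], r[1])
                 for r in reads]
    hits_by_read: dict[str, list[AlignmentHit]] = {}
    for rid, seq in items:
        raw: list[AlignmentHit] = []
        for tid, ref in references.items():
            for s, mm in _occurrences(seq, ref, max_mismatches):
                raw.append(AlignmentHit(rid, tid, s, s + len(seq), "+", mm))
            if search_revcomp:
                rc = revcomp(seq)
                for s, mm in _occurrences(rc, ref, max_mismatches):
                    raw.append(AlignmentHit(rid, tid, s, s + len(seq), "-", mm))
        if raw:
            best = min(h.mismatches for h in raw)
            raw = [h for h in raw if h.mismatches == best]
        hits_by_read[rid] = raw
    return weight_multimappers(hits_by_read)


def weight_multimappers(
    hits_by_read: dict[str, list[AlignmentHit]]
) -> dict[str, list[AlignmentHit]]:
    """Assign weight 1/k to each of a read's k hits (weights sum to 1)."""
    return {
        rid: [replace(h, weight=1.0 / len(hits)) for h in hits]
        for rid, hits in hits_by_read.items()
    }


def annotate(
    hits_by_read: dict[str, list[AlignmentHit]],
    bundle: ReferenceBundle,
    mature_extension: int = 2,
    all_read_ids: list[str] | None = None,
) -> list[AnnotatedRead]:
    """Assign one category per hit; optionally emit 'unmapped' entries for
    reads in ``all_read_ids`` that have no hits."""
    mature_windows: dict[str, list[tuple[int, int, str]]] = {}
    for m in bundle.matures:
        mature_windows.setdefault(m.hairpin_id, []).append((m.start, m.end, m.mature_id))
    genome_windows: list[tuple[int, int, str]] = []
    for m in bundle.matures:
        try:
            gs, ge = bundle.mature_genome_window(m.mature_id)
        except KeyError:
            continue
        genome_windows.append((gs, ge, m.mature_id))

    out: list[AnnotatedRead] = []
    for rid, hits in hits_by_read.items():
        for h in hits:
            cat, mid = _classify_hit(h, bundle, mature_windows, genome_windows, mature_extension)
            out.append(AnnotatedRead(rid, cat, mid, h.weight, h.target_id, h.start, h.end))
    if all_read_ids is not None:
        mapped = {rid for rid, hits in hits_by_read.items() if hits}
        for rid in all_read_ids:
            if rid not in mapped:
                out.append(AnnotatedRead(rid, "unmapped", None, 1.0))
    return out


def _classify_hit(h, bundle, mature_windows, genome_windows, ext):
    if h.target_id in bundle.hairpins:
        for ms, me, mid in mature_windows.get(h.target_id, []):
            if ms - ext <= h.start and h.end <= me + ext:
                return "miRNA", mid
        return _CLS_TO_CATEGORY["miRNA_hairpin"], None
    # genome hit: mature windows projected onto the toy chromosome first
    for gs, ge, mid in genome_windows:
        if gs - ext <= h.start and h.end <= ge + ext:
            return "miRNA", mid
    containing = [f for f in bundle.features if f.start <= h.start and h.end <= f.end]
    if containing:
        cats = {_CLS_TO_CATEGORY[f.cls] for f in containing}
        for cat in CATEGORY_PRIORITY:
            if cat in cats:
                return cat, None
    return "unannotated", None


def composition_summary(annotated: list[AnnotatedRead]) -> dict:
    """Weighted per-category fractions over mapped reads, plus the
    mapped/unique/multi/unmapped read fractions of the library."""
    mapped_w: dict[str, float] = {}
    read_max_w: dict[str, float] = {}
    n_unmapped = 0
    read_seen: set[str] = set()
    for a in annotated:
        if a.category == "unmapped":
            n_unmapped += 1
            read_seen.add(a.read_id)
            continue
        mapped_w[a.category] = mapped_w.get(a.category, 0.0) + a.weight
        read_max_w[a.read_id] = max(read_max_w.get(a.read_id, 0.0), a.weight)
        read_seen.add(a.read_id)
    total_mapped_w = sum(mapped_w.values())
    n_total = len(read_seen)
    n_mapped = len(read_max_w)
    n_unique = sum(1 for w in read_max_w.values() if w == 1.0)
    if total_mapped_w == 0:
        return {"category_fractions": {}, "empty": True,
                "mapped_fraction": 0.0, "unique_fraction": 0.0,
                "multi_fraction": 0.0, "unmapped_fraction": 1.0 if n_total else 0.0}
    return {
        "category_fractions": {c: w / total_mapped_w for c, w in sorted(mapped_w.items())},
        "empty": False,
        "mapped_fraction": n_mapped / n_total if n_total else 0.0,
        "unique_fraction": n_unique / n_total if n_total else 0.0,
        "multi_fraction": (n_mapped - n_unique) / n_total if n_total else 0.0,
        "unmapped_fraction": n_unmapped / n_total if n_total else 0.0,
    }


def length_firstbase_profile(
    reads: list[ReadRecord] | list[tuple[str, str]],
    hits_by_read: dict[str, list[AlignmentHit]] | None = None,
    restrict: str = "all",
) -> pd.DataFrame:
    """Length x 5'-base matrix of read counts (one unit per read).

    ``restrict='hairpin-mapped'`` keeps only reads with at least one hit in
    ``hits_by_read`` (pass hairpin-alignment hits for the canonical profile).
    """
    items = [(r.read_id, r.sequence) if isinstance(r, ReadRecord) else (r[0], r[1])
             for r in reads]
    if restrict == "hairpin-mapped":
        if hits_by_read is None:
            raise ValueError("hits_by_read required for restrict='hairpin-mapped'")
        items = [(rid, s) for rid, s in items if hits_by_read.get(rid)]
    if not items:
        return pd.DataFrame(columns=list("ACGT"), dtype=float)
    lengths = sorted({len(s) for _, s in items})
    mat = pd.DataFrame(0.0, index=lengths, columns=list("ACGT"))
    for _, s in items:
        if s and s[0] in "ACGT":
            mat.loc[len(s), s[0]] += 1.0
    mat.index.name = "length"
    return mat
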