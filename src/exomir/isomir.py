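"""3' isomiR classification by iterative trim-and-remap.

Reads are confronted with the hairpin set first; reads that instead match the
toy genome are set aside as non-miRNA, and everything still unmapped is
trimmed one 3' nucleotide at a time (up to ``rounds`` times, default 10) and
re-mapped to hairpins with 0 mismatches. The removed 3' suffix of a read that
eventually maps is split against the hairpin continuation into a templated
part and a non-templated addition (NTA). Because mapping is maximal-prefix,
a templated tail can only be declared beyond the canonical mature 3' end — a
templated re-extension after trimming is indistinguishable from less
trimming, and that reading is adopted deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .mapanno import revcomp
from .readprep import ReadRecord
from .reference import ReferenceBundle

STATUSES = ("intact", "trimmed", "tailed", "trimmed+tailed", "unclassified")


@dataclass(frozen=True)
class TrimMapResult:
    read_id: str
    hairpin_id: str
    start: int
    end: int
    removed_suffix: str
    rounds_used: int
    weight: float


@dataclass(frozen=True)
class IsomiRCall:
    read_id: str
    mature_id: str
    trim_len: int
    tail_seq: str
    tail_templated_len: int
    nta_seq: str
    status: str
    rounds_used: int
    weight: float = 1.0


@dataclass
class ClassificationResult:
    calls: list[IsomiRCall]
    unattributed: list[TrimMapResult]
    unclassified_ids: list[str]
    genomic_ids: list[str]
    n_input: int = 0


class HairpinIndex:
    """Exact-substring index over the hairpin set, built lazily per length."""

    def __init__(self, hairpins: dict[str, str]):
        self.hairpins = hairpins
        self._by_len: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def lookup(self, seq: str) -> list[tuple[str, int]]:
        idx = self._by_len.get(len(seq))
        if idx is None:
            idx = {}
            n = len(seq)
            for hid, hp in self.hairpins.items():
                for s in range(len(hp) - n + 1):
                    idx.setdefault(hp[s:s + n], []).append((hid, s))
            self._by_len[len(seq)] = idx
        return idx.get(seq, [])


def iterative_trim_map(
    reads: list[ReadRecord] | list[tuple[str, str]],
    bundle: ReferenceBundle,
    rounds: int = 10,
    min_len: int = 15,
    genome_screen: bool = True,
    high_confidence_only: bool = False,
) -> tuple[list[TrimMapResult], list[str], list[str], int]:
    """Map each read's longest 3'-trimmed prefix to the hairpins.

    Returns ``(placements, unclassified_ids, genomic_ids, n_input)``.
    A read maps at the first round where its current prefix is an exact
    hairpin substring; the bases removed up to that round are recorded
    verbatim. Reads matching only the genome at full length are screened out;
    reads still unmapped after ``rounds`` trims (or falling below ``min_len``)
    are unclassified.
    """
    hairpins = bundle.hairpins
    if high_confidence_only:
        keep_hp = {m.hairpin_id for m in bundle.matures if m.mature_id in bundle.high_confidence}
        hairpins = {h: s for h, s in hairpins.items() if h in keep_hp}
    index = HairpinIndex(hairpins)
    items = [(r.read_id, r.sequence) if isinstance(r, ReadRecord) else (r[0], r[1])
             for r in reads]

    placements: list[TrimMapResult] = []
    unclassified: list[str] = []
    genomic: list[str] = []
    for rid, seq in items:
        if len(seq) < min_len:
            unclassified.append(rid)
            continue
        hits0 = index.lookup(seq)
        if hits0:
            _emit(placements, rid, seq, hits0, 0)
            continue
        if genome_screen and (seq in bundle.genome or revcomp(seq) in bundle.genome):
            genomic.append(rid)
            continue
        placed = False
        for r in range(1, rounds + 1):
            prefix = seq[:len(seq) - r]
            if len(prefix) < min_len:
                break
            hits = index.lookup(prefix)
            if hits:
                _emit(placements, rid, prefix, hits, r, removed=seq[len(seq) - r:])
                placed = True
                break
        if not placed:
            unclassified.append(rid)
    return placements, unclassified, genomic, len(items)


def _emit(placements, rid, mapped_seq, hits, rounds_used, removed=""):
    w = 1.0 / len(hits)
    for hid, s in hits:
        placements.append(
            TrimMapResult(rid, hid, s, s + len(mapped_seq), removed, rounds_used, w)
        )


def resolve_tail(
    placement: TrimMapResult,
    bundle: ReferenceBundle,
    mature_extension: int = 2,
) -> IsomiRCall | None:
    """Turn a hairpin placement plus removed suffix into an isomiR call.

    ``trim_len`` is measured against the canonical mature 3' end; the removed
    suffix is split into the longest prefix matching the hairpin continuation
    (templated) and the non-templated remainder. Placements outside every
    extended mature window are not attributed (returns None).
    """
    hp = bundle.hairpins[placement.hairpin_id]
    candidates = [
        m for m in bundle.matures_of(placement.hairpin_id)
        if m.start - mature_extension <= placement.start
        and placement.end <= m.end + mature_extension
        and abs(placement.start - m.start) <= mature_extension
    ]
    if not candidates:
        return None
    m = min(candidates, key=lambda c: abs(placement.start - c.start))
    trim_len = max(0, m.end - placement.end)
    extension = max(0, placement.end - m.end)  # mapped templated tail beyond canonical end
    ext_seq = hp[m.end:placement.end] if extension else ""
    cont = hp[placement.end:]
    lcp = 0
    for a, b in zip(placement.removed_suffix, cont):
        if a != b:
            break
        lcp += 1
    tail_seq = ext_seq + placement.removed_suffix
    nta_seq = placement.removed_suffix[lcp:]
    if trim_len == 0 and not tail_seq:
        status = "intact"
    elif tail_seq and trim_len > 0:
        status = "trimmed+tailed"
    elif tail_seq:
        status = "tailed"
    else:
        status = "trimmed"
    return IsomiRCall(placement.read_id, m.mature_id, trim_len, tail_seq,
                      extension + lcp, nta_seq, status, placement.rounds_used,
                      placement.weight)


def classify_reads(
    reads: list[ReadRecord] | list[tuple[str, str]],
    bundle: ReferenceBundle,
    rounds: int = 10,
    min_len: int = 15,
    mature_extension: int = 2,
    genome_screen: bool = True,
    high_confidence_only: bool = False,
) -> ClassificationResult:
    placements, unclassified, genomic, n_input = iterative_trim_map(
        reads, bundle, rounds, min_len, genome_screen, high_confidence_only
    )
    calls, unattributed = [], []
    for p in placements:
        call = resolve_tail(p, bundle, mature_extension)
        if call is None:
            unattributed.append(p)
        else:
            calls.append(call)
    return ClassificationResult(calls, unattributed, unclassified, genomic, n_input)


def trim_tail_summary(calls: list[IsomiRCall]) -> tuple[dict[str, float], pd.DataFrame]:
    """Pooled weighted fractions per 3'-status, plus the per-miRNA
    trim-length x tail-category matrix (the heat-map analog)."""
    if not calls:
        return {"empty": True}, pd.DataFrame()
    rows = [
        dict(mature_id=c.mature_id, status=c.status, trim_len=c.trim_len,
             tail_cat=("none" if not c.tail_seq else
                       "nta" if c.nta_seq else "templated"),
             weight=c.weight)
        for c in calls
    ]
    df = pd.DataFrame(rows)
    total = df.weight.sum()
    fractions = {s: float(df.loc[df.status == s, "weight"].sum() / total)
                 for s in STATUSES[:4]}
    heat = (df.pivot_table(index="mature_id", columns=["trim_len", "tail_cat"],
                           values="weight", aggfunc="sum", fill_value=0.0))
    heat = heat.div(heat.sum(axis=1), axis=0)
    return fractions, heat


def detect_5prime_variants(
    calls_or_placements: list[TrimMapResult],
    bundle: ReferenceBundle,
    mature_extension: int = 2,
) -> pd.DataFrame:
    """Per-miRNA weighted histogram of 5' start offsets (-2..+2 relative to
    the canonical mature start)."""
    offsets = range(-mature_extension, mature_extension + 1)
    counts: dict[str, dict[int, float]] = {}
    for p in calls_or_placements:
        for m in bundle.matures_of(p.hairpin_id):
            off = p.start - m.start
            if abs(off) <= mature_extension:
                counts.setdefault(m.mature_id, {o: 0.0 for o in offsets})[off] += p.weight
                break
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0.0)
    df = df.reindex(columns=list(offsets), fill_value=0.0)
    return df.div(df.sum(axis=1), axis=0)


def nta_profile(
    reads_by_compartment: dict[str, list[ReadRecord] | list[tuple[str, str]]],
    bundle: ReferenceBundle,
    max_nta: int = 3,
    min_len: int = 18,
    min_count: float = 500.0,
) -> pd.DataFrame:
    """Non-templated-addition composition per tail position.

    Only reads of at least ``min_len`` nt that fail both hairpin and genome
    mapping at full length enter; at most ``max_nta`` 3'-trims are attempted.
    miRNAs with fewer than ``min_count`` weighted reads in any compartment are
    dropped from the comparison. Returns a tidy frame (mirna, compartment,
    tail_pos, base, fraction).
    """
    totals: dict[tuple[str, str], float] = {}
    nta_counts: dict[tuple[str, str, int, str], float] = {}
    for comp, reads in reads_by_compartment.items():
        items = [(r.read_id, r.sequence) if isinstance(r, ReadRecord) else (r[0], r[1])
                 for r in reads]
        long_enough = [(rid, s) for rid, s in items if len(s) >= min_len]
        res = classify_reads(long_enough, bundle, rounds=max_nta, min_len=min_len)
        for c in res.calls:
            totals[(c.mature_id, comp)] = totals.get((c.mature_id, comp), 0.0) + c.weight
            for k, base in enumerate(c.nta_seq, start=1):
                key = (c.mature_id, comp, k, base)
                nta_counts[key] = nta_counts.get(key, 0.0) + c.weight
    comps = list(reads_by_compartment)
    keep = {m for (m, _c) in totals
            if all(totals.get((m, c), 0.0) >= min_count for c in comps)}
    rows = []
    for (m, comp, pos, base), w in sorted(nta_counts.items()):
        if m in keep:
            rows.append(dict(mirna=m, compartment=comp, tail_pos=pos, base=base, weight=w))
    if not rows:
        return pd.DataFrame(columns=["mirna", "compartment", "tail_pos", "base", "fraction"])
    df = pd.DataFrame(rows)
    df["fraction"] = df.weight / df.groupby(["mirna", "compartment", "tail_pos"])["weight"].transform("sum")
    return df.drop(columns="weight")
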