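"""Simulate small-RNA cell/exosome libraries with per-read ground truth.

Each simulated library draws read sources from a multinomial over mature
miRNAs (with optional compartment-dependent export bias), ncRNA/repeat
fragment classes, and an unmappable remainder. miRNA-derived reads carry
known 3' trimming, templated or non-templated tailing, and optional 5'
offsets; the 3' sequencing adapter is appended in full and the read is
truncated to the configured read length, so adapter trimming is exercised
realistically. A truth table records every modification.

Conventions: references and reads are DNA-space (T, not U); qualities are a
constant high value because the downstream analysis never uses them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import DNA, NCRNA_CLASSES, ReferenceBundle

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_MAX_NTA = 3
_MAX_TEMPLATED_TAIL = 2  # longer templated tails would leave the +/-2 annotation window


@dataclass
class TailModel:
    """3' tail generator: length distribution, NTA base composition, and the
    fraction of tails that are templated (copied from the hairpin)."""

    length_probs: tuple[float, ...] = (0.8, 0.12, 0.05, 0.03)  # lengths 0..3
    composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "T": 0.2, "C": 0.2, "G": 0.1}
    )
    templated_fraction: float = 0.2


@dataclass
class LibraryProfile:
    condition: str = "WT"
    compartment: str = "cell"  # "cell" | "exosome"
    read_count: int = 10000
    abundances: dict[str, float] | None = None  # mature_id -> expected weight
    export_log2_bias: dict[str, float] = field(default_factory=dict)
    trim_probs: tuple[float, ...] = (0.7, 0.1, 0.06, 0.05, 0.03, 0.02, 0.02, 0.01, 0.005, 0.003, 0.002)
    tail: TailModel = field(default_factory=TailModel)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"tRNA": 0.08, "rRNA": 0.05, "snRNA": 0.02, "repeat": 0.08, "other": 0.02}
    )
    unmappable_fraction: float = 0.05
    five_prime_offset_probs: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    fragment_length: tuple[int, int] = (16, 32)
    replicate_dispersion: float = 0.0  # gamma CV^2 of per-replicate abundance jitter
    seed: int = 0

    def validate(self, ref: ReferenceBundle) -> None:
        fracs = list(self.class_fractions.values()) + [self.unmappable_fraction]
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        known = {m.mature_id for m in ref.matures}
        if self.abundances:
            bad = set(self.abundances) - known
            if bad:
                raise ValueError(f"unknown mature ids in profile: {sorted(bad)}")
            if any(a < 0 for a in self.abundances.values()):
                raise ValueError("abundances must be >= 0")
        mat_len = min(m.end - m.start for m in ref.matures)
        if len(self.trim_probs) - 1 >= mat_len:
            raise ValueError("trim length may not reach the mature length")
        if not all(abs(o) <= 2 for o in self.five_prime_offset_probs):
            raise ValueError("5' offsets limited to +/-2")


def simulate_library(
    ref: ReferenceBundle, profile: LibraryProfile
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Return ``(reads, truth)``: reads as (id, sequence, quality) triples and
    a truth table with one row per read."""
    profile.validate(ref)
    rng = np.random.default_rng(profile.seed)

    abundances = dict(profile.abundances) if profile.abundances else {
        m.mature_id: 10.0 for m in ref.matures
    }
    if profile.replicate_dispersion > 0:
        d = profile.replicate_dispersion
        for k in abundances:
            abundances[k] *= rng.gamma(1.0 / d, d)
    if profile.compartment == "exosome":
        for k, b in profile.export_log2_bias.items():
            if k in abundances:
                abundances[k] *= 2.0 ** b

    sources: list[tuple[str, str]] = []  # (kind, id)
    probs: list[float] = []
    mirna_frac = 1.0 - sum(profile.class_fractions.values()) - profile.unmappable_fraction
    total_ab = sum(abundances.values())
    for mid, a in abundances.items():
        if a > 0:
            sources.append(("miRNA", mid))
            probs.append(mirna_frac * a / total_ab)
    feats_by_cls = {cls: [f for f in ref.features if f.cls == cls] for cls in NCRNA_CLASSES}
    for cls, frac in profile.class_fractions.items():
        feats = feats_by_cls.get(cls, [])
        for f in feats:
            sources.append((cls, f.feature_id))
            probs.append(frac / len(feats))
    if profile.unmappable_fraction > 0:
        sources.append(("unmappable", ""))
        probs.append(profile.unmappable_fraction)
    probs_arr = np.asarray(probs)
    probs_arr = probs_arr / probs_arr.sum()
    counts = rng.multinomial(profile.read_count, probs_arr)

    trim_lens = np.arange(len(profile.trim_probs))
    tail_lens = np.arange(len(profile.tail.length_probs))
    offsets = sorted(profile.five_prime_offset_probs)
    offset_p = np.array([profile.five_prime_offset_probs[o] for o in offsets], dtype=float)
    offset_p /= offset_p.sum()
    comp_bases = sorted(profile.tail.composition)
    comp_p = np.array([profile.tail.composition[b] for b in comp_bases], dtype=float)
    comp_p /= comp_p.sum()

    reads: list[tuple[str, str, str]] = []
    rows: list[dict] = []
    idx = 0
    order = np.repeat(np.arange(len(sources)), counts)
    rng.shuffle(order)
    for src_i in order:
        kind, sid = sources[src_i]
        idx += 1
        rid = f"read{idx:06d}"
        if kind == "miRNA":
            insert, row = _mirna_read(
                ref, sid, rng, trim_lens, tail_lens, offsets, offset_p, comp_bases, comp_p, profile
            )
        elif kind == "unmappable":
            insert = _unmappable(ref, rng, 22)
            row = dict(source_class="unmappable", feature_id="", mature_id="",
                       five_prime_offset=0, trim_len=0, tail_seq="",
                       tail_templated=False, tail_templated_len=0)
        else:
            f = next(x for x in ref.features if x.feature_id == sid)
            lo, hi = profile.fragment_length
            flen = min(int(rng.integers(lo, hi + 1)), f.end - f.start)
            fstart = f.start + int(rng.integers(0, f.end - f.start - flen + 1))
            insert = ref.genome[fstart:fstart + flen]
            row = dict(source_class=kind, feature_id=sid, mature_id="",
                       five_prime_offset=0, trim_len=0, tail_seq="",
                       tail_templated=False, tail_templated_len=0)
        seq = (insert + profile.adapter)[: profile.read_length]
        reads.append((rid, seq, "I" * len(seq)))
        row.update(read_id=rid, insert_len=len(insert))
        rows.append(row)

    truth = pd.DataFrame(rows)[
        ["read_id", "source_class", "feature_id", "mature_id", "five_prime_offset",
         "trim_len", "tail_seq", "tail_templated", "tail_templated_len", "insert_len"]
    ]
    return reads, truth


def _mirna_read(ref, mature_id, rng, trim_lens, tail_lens, offsets, offset_p,
                comp_bases, comp_p, profile: LibraryProfile):
    m = ref.mature_by_id(mature_id)
    hp = ref.hairpins[m.hairpin_id]
    off = int(rng.choice(offsets, p=offset_p)) if len(offsets) > 1 else offsets[0]
    trim = int(rng.choice(trim_lens, p=np.asarray(profile.trim_probs) / sum(profile.trim_probs)))
    tail_len = int(rng.choice(tail_lens, p=np.asarray(profile.tail.length_probs)
                              / sum(profile.tail.length_probs)))
    end = m.end - trim
    insert = hp[m.start + off:end]

    templated = False
    tail = ""
    if tail_len > 0:
        # templated tails are only drawn for untrimmed molecules: after a trim
        # a templated re-extension is indistinguishable from less trimming
        templated = trim == 0 and rng.random() < profile.tail.templated_fraction
        if templated:
            tail_len = min(tail_len, _MAX_TEMPLATED_TAIL, len(hp) - end)
            tail = hp[end:end + tail_len]
            if not tail:
                templated = False
        if not templated:
            bases = []
            for k in range(tail_len):
                template_next = hp[end + k] if end + k < len(hp) else ""
                b = str(rng.choice(comp_bases, p=comp_p))
                while b == template_next:  # force genuinely non-templated bases
                    b = str(rng.choice(list(set(DNA) - {template_next})))
                bases.append(b)
            tail = "".join(bases)
    return insert + tail, dict(
        source_class="miRNA", feature_id=m.hairpin_id, mature_id=mature_id,
        five_prime_offset=off, trim_len=trim, tail_seq=tail,
        tail_templated=templated, tail_templated_len=len(tail) if templated else 0,
    )


def _unmappable(ref: ReferenceBundle, rng: np.random.Generator, n: int) -> str:
    from .mapanno import revcomp

    for _ in range(100):
        seq = "".join(rng.choice(list(DNA), size=n))
        if seq not in ref.genome and revcomp(seq) not in ref.genome:
            return seq
    raise RuntimeError("could not draw an unmappable read")


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        q = "".join(chr(c + 33) for c in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), q))
    return out
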