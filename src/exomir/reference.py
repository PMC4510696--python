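"""Synthetic reference world: hairpins, mature windows, and a toy genome.

The bundle plays the role that miRBase hairpins plus a genome assembly play
for real small-RNA data: hairpin sequences are embedded verbatim in a single
toy chromosome alongside tRNA/rRNA/snRNA/repeat loci, so reads simulated from
mature windows can be recovered by hairpin-first, genome-second mapping.

All coordinates are 0-based half-open internally; GFF3 output follows the
1-based inclusive convention.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
NCRNA_CLASSES = ("tRNA", "rRNA", "snRNA", "repeat", "other")
FEATURE_CLASSES = ("miRNA_hairpin",) + NCRNA_CLASSES

# typical locus lengths for each simulated ncRNA class (nt)
_CLASS_LENGTHS = {"tRNA": 75, "rRNA": 120, "snRNA": 105, "repeat": 200, "other": 90}


@dataclass(frozen=True)
class Mature:
    """A mature miRNA window on its hairpin (0-based half-open)."""

    mature_id: str
    hairpin_id: str
    start: int
    end: int
    arm: str  # "5p" or "3p"


@dataclass(frozen=True)
class Feature:
    """A genome feature interval (0-based half-open, single toy chromosome)."""

    feature_id: str
    cls: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class ReferenceBundle:
    hairpins: dict[str, str]
    matures: list[Mature]
    genome: str
    features: list[Feature]
    high_confidence: frozenset[str] = field(default_factory=frozenset)
    chrom: str = "toy1"

    def mature_sequence(self, mature_id: str) -> str:
        m = self.mature_by_id(mature_id)
        return self.hairpins[m.hairpin_id][m.start:m.end]

    def mature_by_id(self, mature_id: str) -> Mature:
        for m in self.matures:
            if m.mature_id == mature_id:
                return m
        raise KeyError(mature_id)

    def matures_of(self, hairpin_id: str) -> list[Mature]:
        return [m for m in self.matures if m.hairpin_id == hairpin_id]

    def hairpin_genome_start(self, hairpin_id: str) -> int:
        for f in self.features:
            if f.feature_id == hairpin_id and f.cls == "miRNA_hairpin":
                return f.start
        raise KeyError(hairpin_id)

    def mature_genome_window(self, mature_id: str) -> tuple[int, int]:
        m = self.mature_by_id(mature_id)
        off = self.hairpin_genome_start(m.hairpin_id)
        return off + m.start, off + m.end

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for m in self.matures:
            hp = self.hairpins[m.hairpin_id]
            if not (0 <= m.start < m.end <= len(hp)):
                raise ValueError(f"mature {m.mature_id} outside hairpin {m.hairpin_id}")
        for f in self.features:
            if f.cls == "miRNA_hairpin":
                if self.genome[f.start:f.end] != self.hairpins[f.feature_id]:
                    raise ValueError(f"hairpin {f.feature_id} not verbatim in genome")
        by_cls: dict[str, list[Feature]] = {}
        for f in self.features:
            by_cls.setdefault(f.cls, []).append(f)
        for cls, feats in by_cls.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping {cls} features {a.feature_id}/{b.feature_id}")
        unknown = self.high_confidence - {m.mature_id for m in self.matures}
        if unknown:
            raise ValueError(f"high_confidence ids not in bundle: {sorted(unknown)}")


@dataclass
class ReferenceConfig:
    n_hairpins: int = 20
    hairpin_length: tuple[int, int] = (70, 90)
    mature_length: int = 22
    both_arms: bool = False
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"tRNA": 3, "rRNA": 2, "snRNA": 2, "repeat": 3, "other": 2}
    )
    gap_length: tuple[int, int] = (25, 60)
    # number of hairpins at the front of the list sharing one identical
    # sequence (multi-mapper stress); 0 disables
    n_shared_hairpin_copies: int = 0
    high_confidence_fraction: float = 1.0
    seed: int = 0
    max_retries: int = 50


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def build_reference(config: ReferenceConfig | None = None, **kwargs) -> ReferenceBundle:
    """Build a deterministic synthetic reference bundle.

    Mature windows are rejection-sampled so each mature sequence occurs at
    exactly one genome locus, unless ``n_shared_hairpin_copies`` requests
    identical hairpins for multi-mapper tests.
    """
    cfg = config or ReferenceConfig(**kwargs)
    if config is not None and kwargs:
        cfg = dataclasses.replace(config, **kwargs)
    if cfg.n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    if cfg.hairpin_length[0] < cfg.mature_length + 10:
        raise ValueError("hairpin length must be >= mature length + 10")
    rng = np.random.default_rng(cfg.seed)

    for _attempt in range(cfg.max_retries):
        bundle = _assemble(cfg, rng)
        if _matures_unique(bundle, cfg):
            bundle.validate()
            return bundle
    raise RuntimeError(
        "could not satisfy mature-sequence uniqueness after "
        f"{cfg.max_retries} attempts (constraint: each mature sequence occurs "
        "at exactly one genome locus)"
    )


def _assemble(cfg: ReferenceConfig, rng: np.random.Generator) -> ReferenceBundle:
    hairpins: dict[str, str] = {}
    matures: list[Mature] = []
    shared_seq: str | None = None
    shared_matures: list[Mature] | None = None
    for i in range(cfg.n_hairpins):
        hid = f"hp{i + 1}"
        if cfg.n_shared_hairpin_copies >= 2 and i < cfg.n_shared_hairpin_copies and shared_seq:
            hairpins[hid] = shared_seq
            for j, m in enumerate(shared_matures):
                matures.append(dataclasses.replace(m, mature_id=f"{hid}-{m.arm}", hairpin_id=hid))
            continue
        hlen = int(rng.integers(cfg.hairpin_length[0], cfg.hairpin_length[1] + 1))
        seq = _random_dna(rng, hlen)
        hairpins[hid] = seq
        # keep >=5 nt margins so 5' offsets and 3' templated tails stay inside
        mstart = 5
        hp_matures = [Mature(f"{hid}-5p", hid, mstart, mstart + cfg.mature_length, "5p")]
        if cfg.both_arms:
            m3 = hlen - 5 - cfg.mature_length
            hp_matures.append(Mature(f"{hid}-3p", hid, m3, m3 + cfg.mature_length, "3p"))
        matures.extend(hp_matures)
        if cfg.n_shared_hairpin_copies >= 2 and i == 0:
            shared_seq, shared_matures = seq, hp_matures

    features_seq: list[tuple[str, str, str]] = [  # (id, class, sequence)
        (hid, "miRNA_hairpin", seq) for hid, seq in hairpins.items()
    ]
    for cls in NCRNA_CLASSES:
        for j in range(cfg.n_per_class.get(cls, 0)):
            n = _CLASS_LENGTHS[cls] + int(rng.integers(-10, 11))
            features_seq.append((f"{cls}{j + 1}", cls, _random_dna(rng, n)))
    rng.shuffle(features_seq)

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for fid, cls, seq in features_seq:
        gap = _random_dna(rng, int(rng.integers(cfg.gap_length[0], cfg.gap_length[1] + 1)))
        parts.append(gap)
        pos += len(gap)
        parts.append(seq)
        features.append(Feature(fid, cls, pos, pos + len(seq)))
        pos += len(seq)
    parts.append(_random_dna(rng, int(rng.integers(*cfg.gap_length))))
    genome = "".join(parts)

    mature_ids = [m.mature_id for m in matures]
    n_hc = max(1, int(round(cfg.high_confidence_fraction * len(mature_ids))))
    high_conf = frozenset(mature_ids[:n_hc])
    return ReferenceBundle(hairpins, matures, genome, features, high_conf)


def _matures_unique(bundle: ReferenceBundle, cfg: ReferenceConfig) -> bool:
    expected_shared = max(cfg.n_shared_hairpin_copies, 1)
    shared_ids = {
        m.mature_id
        for m in bundle.matures
        if cfg.n_shared_hairpin_copies >= 2
        and int(m.hairpin_id[2:]) <= cfg.n_shared_hairpin_copies
    }
    for m in bundle.matures:
        seq = bundle.mature_sequence(m.mature_id)
        want = expected_shared if m.mature_id in shared_ids else 1
        if _count_occurrences(bundle.genome, seq) != want:
            return False
    return True


def _count_occurrences(text: str, pattern: str) -> int:
    n, i = 0, text.find(pattern)
    while i != -1:
        n += 1
        i = text.find(pattern, i + 1)
    return n


# ---------------------------------------------------------------------------
# FASTA / GFF3 round-trip


def write_reference(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hairpins": outdir / "hairpins.fa",
        "genome": outdir / "genome.fa",
        "matures": outdir / "matures.gff3",
        "features": outdir / "features.gff3",
        "high_confidence": outdir / "high_confidence.txt",
    }
    SeqIO.write(
        [SeqRecord(Seq(s), id=h, description="") for h, s in bundle.hairpins.items()],
        paths["hairpins"], "fasta",
    )
    SeqIO.write([SeqRecord(Seq(bundle.genome), id=bundle.chrom, description="")],
                paths["genome"], "fasta")
    with open(paths["matures"], "w") as fh:
        fh.write("##gff-version 3\n")
        for m in bundle.matures:
            fh.write(
                f"{m.hairpin_id}\texomir\tmiRNA\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                f"ID={m.mature_id};arm={m.arm}\n"
            )
    with open(paths["features"], "w") as fh:
        fh.write("##gff-version 3\n")
        for f in bundle.features:
            fh.write(
                f"{bundle.chrom}\texomir\t{f.cls}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.feature_id}\n"
            )
    paths["high_confidence"].write_text("".join(f"{m}\n" for m in sorted(bundle.high_confidence)))
    return paths


def read_reference(refdir: str | Path) -> ReferenceBundle:
    refdir = Path(refdir)
    hairpins = {r.id: str(r.seq).upper() for r in SeqIO.parse(refdir / "hairpins.fa", "fasta")}
    genome_rec = next(SeqIO.parse(refdir / "genome.fa", "fasta"))
    matures, features = [], []
    for line in (refdir / "matures.gff3").read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        seqid, _, _, start, end, _, _, _, attrs = line.split("\t")
        a = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        matures.append(Mature(a["ID"], seqid, int(start) - 1, int(end), a.get("arm", "5p")))
    for line in (refdir / "features.gff3").read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        _, _, cls, start, end, _, strand, _, attrs = line.split("\t")
        a = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        features.append(Feature(a["ID"], cls, int(start) - 1, int(end), strand))
    hc_path = refdir / "high_confidence.txt"
    hc = frozenset(hc_path.read_text().split()) if hc_path.exists() else frozenset()
    bundle = ReferenceBundle(hairpins, matures, str(genome_rec.seq).upper(), features, hc,
                             chrom=genome_rec.id)
    bundle.validate()
    return bundle
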