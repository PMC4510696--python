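"""Deterministic IUPAC motif scanning over miRNA sequence sets.

Scans candidate exosome-sorting motifs (e.g. GGAG, the hnRNP A2B1-bound
signal) across mature sequences, optionally restricted to a 3'-terminal
window, and compares motif incidence between two sequence sets with a
one-sided hypergeometric test. U and T are equivalent: everything is
normalized to DNA space before matching.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif: str
    start: int  # 0-based from the 5' end
    distance_from_3p: int  # seq length - match end
    matched: str


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _sets(motif: str) -> list[str]:
    out = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif {motif!r}")
        out.append(IUPAC[ch])
    return out


def scan(
    seqs: dict[str, str] | list[tuple[str, str]],
    motif: str,
    three_prime_window: int | None = None,
) -> list[MotifHit]:
    """All (overlapping) motif matches; with ``three_prime_window=k`` only
    hits whose end lies within the final k nt are kept."""
    sets = _sets(motif)
    m = len(sets)
    if three_prime_window is not None and three_prime_window < m:
        raise ValueError("window must be at least the motif length")
    items = seqs.items() if isinstance(seqs, dict) else seqs
    hits = []
    for sid, seq in items:
        s = _normalize(seq)
        for i in range(len(s) - m + 1):
            sub = s[i:i + m]
            if all(b in allowed for b, allowed in zip(sub, sets)):
                dist = len(s) - (i + m)
                if three_prime_window is None or dist <= three_prime_window - m:
                    hits.append(MotifHit(sid, motif.upper(), i, dist, sub))
    return hits


def motif_presence(
    seqs: dict[str, str] | list[tuple[str, str]],
    motif: str,
    three_prime_window: int | None = None,
) -> set[str]:
    """Ids of sequences carrying at least one motif hit."""
    return {h.seq_id for h in scan(seqs, motif, three_prime_window)}


def set_enrichment(
    n_with_a: int, size_a: int, n_with_b: int, size_b: int
) -> dict:
    """2x2 motif-incidence table and one-sided hypergeometric tail p for
    over-representation of the motif in set A."""
    if size_a <= 0 or size_b <= 0:
        raise ValueError("universe sizes must be positive")
    if n_with_a > size_a or n_with_b > size_b:
        raise ValueError("motif counts exceed set sizes")
    universe = size_a + size_b
    total_with = n_with_a + n_with_b
    p = float(stats.hypergeom.sf(n_with_a - 1, universe, total_with, size_a))
    table = [[n_with_a, size_a - n_with_a], [n_with_b, size_b - n_with_b]]
    return {"table": table, "p_value": min(1.0, p), "universe": universe}
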