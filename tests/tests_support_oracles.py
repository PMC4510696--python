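"""Independent pure-Python oracles shared by the test modules."""
from functools import lru_cache

MIN_OVERLAP = 3


@lru_cache(maxsize=None)
def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def dp_find_adapter(seq: str, adapter: str, rate: float):
    """Exhaustive scan over every start, full-vs-prefix placement, edit count."""
    n, m = len(seq), len(adapter)
    best = None
    for s in range(n):
        rest = seq[s:]
        full = min(levenshtein(adapter, rest[:L]) for L in range(len(rest) + 1))
        if full <= int(rate * m) and (best is None or (full, s) < best):
            best = (full, s)
        for alen in range(MIN_OVERLAP, m):
            ed = levenshtein(rest, adapter[:alen])
            if ed <= int(rate * alen) and (best is None or (ed, s) < best):
                best = (ed, s)
    return None if best is None else (best[1], best[0])
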