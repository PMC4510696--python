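"""Scan miRNA sequences for candidate exosome-sorting motifs.

Scans a small synthetic set of mature-length sequences for the hnRNP
A2B1-bound GGAG signal (and the degenerate U/CC motif), restricted to a
3'-terminal window, and compares motif incidence between an 'exported' and a
'retained' set with a hypergeometric test. Sequences here are synthetic
stand-ins constructed so that only the exported set carries the motif.
"""
from exomir import motif_presence, scan, set_enrichment

exported = {
    "exo-mir-1": "AACCCGUAGAUCCGAAGGAGUG",  # GGAG 2 nt from the 3' end
    "exo-mir-2": "UGAGGUAGUAGGUUGGAGAGUU",
    "exo-mir-3": "CAGUGCAAUGUUAAAGGAGUGA",
}
retained = {
    "cell-mir-1": "AACCCGUAGAUCCGAACUUGUG",
    "cell-mir-2": "UGAGGUAGUAGGUUGUAUAGUU",
    "cell-mir-3": "CAGUGCAAUGUUAAAAGUGCUU",
}

for h in scan(exported | retained, "GGAG"):
    print(f"GGAG in {h.seq_id} at position {h.start}, "
          f"{h.distance_from_3p} nt from the 3' end")

with_a = len(motif_presence(exported, "GGAG", three_prime_window=8))
with_b = len(motif_presence(retained, "GGAG", three_prime_window=8))
res = set_enrichment(with_a, len(exported), with_b, len(retained))
print(f"3'-windowed GGAG: {with_a}/{len(exported)} exported vs "
      f"{with_b}/{len(retained)} retained, hypergeometric p = {res['p_value']:.3f}")
print("At this toy scale the p-value cannot be small; with real data the same")
print("counts-based test replaces de novo motif discovery.")

print("U/CC motif hits (IUPAC Y = C or U):",
      sorted({h.seq_id for h in scan(retained, "YCC")}))
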