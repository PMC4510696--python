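"""Recover exosome-sorted miRNAs from a simulated 4-condition experiment.

Simulates two cell lines (WT/MUT oncogene status) x two compartments
(cell/exosome) x 3 replicates, with 20 of 80 miRNAs given a 4-fold export
bias into exosomes. Builds weighted count matrices from the raw reads,
TMM-normalizes, tests exosome vs cell with the NB test, and reports how many
truly exported miRNAs are called at |log2FC| >= 1 and FDR <= 0.001.
"""
import exomir
from exomir.pipeline import (
    ExperimentDesign,
    counts_from_libraries,
    recovery_score,
    simulate_experiment,
    sorting_enrichment,
)

ref = exomir.build_reference(n_hairpins=80, seed=5)
exported = {f"hp{i}-5p" for i in range(1, 21)}
design = ExperimentDesign(read_count=8000,
                          export_log2_bias={m: 2.0 for m in exported}, seed=6)
reads, meta = simulate_experiment(ref, design)
counts = counts_from_libraries(reads, ref, exomir.DEFAULT_ADAPTER)
print(f"count matrix: {counts.shape[0]} miRNAs x {counts.shape[1]} samples")

for cond in design.conditions:
    res = sorting_enrichment(counts, meta, cond)
    score = recovery_score(res, exported)
    print(f"{cond}: {score['n_called']} exosome-enriched calls, "
          f"recall {score['recall']:.2f}, false fraction {score['false_fraction']:.4f}")
print("Recall counts truly exported miRNAs re-identified from raw reads;")
print("the false fraction should stay near the 0.001 FDR target.")

scores, explained, _ = exomir.pca(counts)
print(f"PC1 explains {explained[0]:.2f} of variance; "
      "cell and exosome samples separate along it:")
for sample, pc1 in scores.PC1.items():
    print(f"  {sample:>14}: {pc1:+.1f}")
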