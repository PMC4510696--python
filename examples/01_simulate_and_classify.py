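"""Simulate a small-RNA library with known 3' modifications and classify it.

Builds a toy reference (hairpins embedded in a mini-genome), simulates reads
carrying trimming and non-templated tails plus a ligated 3' adapter, runs
adapter trimming and the iterative trim-and-remap classifier, and prints the
pooled 3'-status fractions next to the simulation's ground truth.
"""
import exomir

ref = exomir.build_reference(n_hairpins=10, seed=1)
profile = exomir.LibraryProfile(read_count=5000, class_fractions={},
                                unmappable_fraction=0.0, seed=2)
reads, truth = exomir.simulate_library(ref, profile)

kept, report = exomir.process_reads(reads, profile.adapter)
print(f"adapter trimming: {report.reads_in} reads in, "
      f"{report.reads_trimmed} trimmed, {report.reads_removed_short} dropped <15 nt")

result = exomir.classify_reads(kept, ref, rounds=10)
fractions, heatmap = exomir.trim_tail_summary(result.calls)
print("classified 3'-status fractions (weighted):")
for status, frac in fractions.items():
    print(f"  {status:>15}: {frac:.3f}")

truth_intact = ((truth.trim_len == 0) & (truth.tail_seq == "")).mean()
print(f"ground-truth intact fraction: {truth_intact:.3f}")
print("The classified fractions should track the simulated modification rates;")
print("reads trimmed below 15 nt never reach the classifier.")
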