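"""Annotate a mixed library into ncRNA classes and profile read lengths.

Simulates a library containing miRNA, tRNA/rRNA/repeat fragments and
unmappable reads, aligns everything to the toy genome (both strands,
multi-mappers weighted 1/k), and prints the weighted class composition plus
the modal read length among hairpin-derived reads.
"""
import exomir

ref = exomir.build_reference(n_hairpins=10, seed=3)
profile = exomir.LibraryProfile(read_count=8000, seed=4)
reads, truth = exomir.simulate_library(ref, profile)
kept, _ = exomir.process_reads(reads, profile.adapter)

hits = exomir.align([(r.read_id, r.sequence) for r in kept],
                    {ref.chrom: ref.genome}, search_revcomp=True)
annotated = exomir.annotate(hits, ref, all_read_ids=[r.read_id for r in kept])
summary = exomir.composition_summary(annotated)

print(f"mapped fraction: {summary['mapped_fraction']:.3f} "
      f"(unique {summary['unique_fraction']:.3f}, multi {summary['multi_fraction']:.3f})")
print("weighted composition of mapped reads:")
for cat, frac in summary["category_fractions"].items():
    print(f"  {cat:>12}: {frac:.3f}")

hp_hits = exomir.align([(r.read_id, r.sequence) for r in kept], ref.hairpins)
profile_mat = exomir.length_firstbase_profile(kept, hp_hits, restrict="hairpin-mapped")
modal = profile_mat.sum(axis=1).idxmax()
print(f"modal length of hairpin-mapped reads: {modal} nt")
print("With low trim/tail rates the modal length equals the 22-nt mature length.")
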