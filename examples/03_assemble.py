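"""One unrefined de novo assembly, end to end, scored against the truth.

Runs the four pipeline steps explicitly — filter+sort, split, all-pairs
alignment, overlap-layout-consensus — on 30x simulated coverage of a
0.8 Mbp reference, then prints the contiguity and internal-consistency
report plus the reference accuracy (weighted mean confidence).
"""

from omsweep import (
    AlignParams, ErrorProfile, ScoreNull, all_pairs_overlaps, assemble_olc,
    filter_molecules, quality_report, random_reference, simulate_molecules,
    sort_molecules, split_molecules,
)

ref = random_reference(800_000, 10.5, seed=3)
ms, _ = simulate_molecules(ref, coverage_fold=30.0, err=ErrorProfile(seed=8))
params = AlignParams(1.5, 0.15, 40.0, 1.11e-4)

filtered = sort_molecules(filter_molecules(ms, min_length_kbp=100, min_labels=6))
chunks = split_molecules(filtered, 4)
null = ScoreNull.fit(ms, params)
overlaps = all_pairs_overlaps(chunks, params, null)
asm = assemble_olc(filtered, overlaps, params=params)
rep = quality_report(asm, filtered, reference=ref, align_params=params)

print(f"input: {len(ms)} molecules, {len(filtered)} after filtering")
print(f"significant overlaps: {len(overlaps)}")
print(f"contigs: {len(asm.contigs)}  placed: {len(asm.placements)}  "
      f"singletons: {len(asm.singletons)}")
print(f"total length: {rep.total_length_bp/1e6:.2f} Mbp  "
      f"N50: {rep.n50_bp/1e3:.0f} kbp  longest: {rep.longest_contig_bp/1e3:.0f} kbp")
print(f"mean label depth: {rep.mean_label_depth:.1f}  "
      f"non-singleton proportion: {rep.nonsingleton_proportion:.2f}")
print(f"weighted mean confidence vs reference: {rep.weighted_mean_confidence:.1f}")
print("\nConfidence is -log10 of the contig-to-reference alignment p-value; "
      "higher means the contig is unlikely to match the reference by chance.")
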