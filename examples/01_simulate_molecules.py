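"""Simulate a nanochannel molecule dataset from a synthetic reference.

Builds a 1 Mbp random reference map at a realistic label density, draws
noisy molecules to 20x coverage under the default error profile, and
prints the realized dataset statistics next to the profile that generated
them — the realized FP/FN rates should match the profile up to sampling
noise.
"""

import numpy as np

from omsweep import ErrorProfile, expected_density, random_reference, simulate_molecules

ref = random_reference(1_000_000, density_per_100kbp=10.5, seed=1)
err = ErrorProfile(fp_per_100kbp=1.5, fn_rate=0.15, sizing_sd_bp_per_kbp=40.0, seed=2)
ms, truth = simulate_molecules(ref, coverage_fold=20.0, err=err)

lengths = np.sort([m.length_bp for m in ms])[::-1]
n50 = lengths[np.searchsorted(np.cumsum(lengths), lengths.sum() / 2)]
n_fp = sum(1 for prov in truth.label_provenance.values() for x in prov if x < 0)

print(f"reference: {ref.length_bp/1e6:.1f} Mbp, {ref.n_labels} labels "
      f"({expected_density(ref):.1f} per 100 kbp)")
print(f"simulated: {len(ms)} molecules, {ms.total_length_bp()/1e6:.1f} Mbp "
      f"({ms.total_length_bp()/ref.length_bp:.0f}x)")
print(f"molecule N50: {n50/1e3:.1f} kbp (generator targets ~165)")
print(f"realized FP density: {n_fp/ms.total_length_bp()*1e5:.2f} per 100 kbp "
      f"(profile: {err.fp_per_100kbp})")
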