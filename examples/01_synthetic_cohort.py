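"""Generate a synthetic holy-basil-like spectral cohort and inspect it.

Builds ~234 reflectance spectra (26 cultivars x 3 cuts x 3 replicates,
355-1700 nm at 2 nm) with matching total phenolic content (TPC)
measurements, then compares mean reflectance between harvest cuts.
"""

import numpy as np

from phenospec import SyntheticConfig, compare_cuts, generate_cohort

config = SyntheticConfig(seed=42)
spectra, records = generate_cohort(config)
tpc = np.array([r.tpc for r in records])

print(f"cohort: {len(spectra)} spectra, {spectra[0].n_bands} bands each")
print(f"TPC: mean {tpc.mean():.4f}, SD {tpc.std(ddof=1):.4f} mg GAE/gDW")
print()
print("cut-wise Welch t-tests on mean reflectance:")
print(compare_cuts(spectra).to_string(index=False))
print()
print("Cut 1 (youngest plants) reflects more light, so its pairs show tiny")
print("p-values; cuts 2 vs 3 are statistically indistinguishable.")
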