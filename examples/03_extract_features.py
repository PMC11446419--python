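"""Compute the 22 statistical features of one reflectance spectrum.

Fourteen time-domain statistics summarize the trace directly; eight more
summarize its band power spectrum (squared DFT magnitudes).
"""

from phenospec import FEATURE_NAMES, SyntheticConfig, extract_all, generate_cohort

spectra, _ = generate_cohort(SyntheticConfig(n_cultivars=2, n_replicates=1, seed=3))
fv = extract_all(spectra)[0]

print(f"sample {fv.sample_id}: 22 features")
for name in FEATURE_NAMES:
    print(f"  {name:<9} {getattr(fv, name):>12.6g}")
print()
print("s_crest (max/RMS), s_form (RMS/mean) and s_pulse (max/mean) satisfy")
print(f"pulse = crest x form: {fv.s_crest * fv.s_form:.6f} == {fv.s_pulse:.6f}")
print("f_* features live on the band power spectrum; f_sum is dominated by")
print("the DC term, the squared sum of all reflectance values.")
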