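"""Microcalcification visibility in the glandular-fraction image.

Two 1 mm hydroxyapatite deposits are embedded in the glandular region; the
contrast-to-noise ratio is compared between the raw count image (where a
deposit is a count deficit) and the GF image (where it is a GF excess).
"""

from glandfrac.evaluate import run_cnr_study

df = run_cnr_study(T=4.0, gfs=(0.3, 0.5), base_seed=0)
print(df.to_string(index=False))
print(f"\nminimum CNR improvement : {df.improvement_pct.min():.1f}%")
# The log-domain GF transform amplifies a deep count deficit relative to
# the Poisson noise floor, so every deposit gains CNR in the GF image.
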