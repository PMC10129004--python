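"""Extract the three acoustic feature spaces from a small corpus.

Bioacoustic (20 expert landmarks), DCT (7 contour-shape coefficients), and
MFCC (192 spectro-temporal summaries); their union deduplicates the shared
duration and HNR columns to 217 features.
"""

import sungkit as sk

cfg = sk.SyntheticConfig(n_calls=60, seed=7, waveforms=True)
corpus, _ = sk.generate_corpus(cfg)

for name in ("bioacoustic", "dct", "mfcc", "union"):
    table = sk.build_feature_table(corpus, name)
    print(f"{name:12s} {len(table.feature_names):3d} features x {len(table)} calls")

call = corpus.calls[0]
print(f"\nDCT parameterization of call {call.call_id} "
      f"({call.call_type}, {call.duration:.3f} s):")
dct = sk.dct_features(call)
print(dct.round(2).to_string())
print("\ndct0 tracks mean pitch, dct1 the rise/fall direction, dct2 the "
      "curvature of the f0 contour; duration and HNR complete the set.")
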