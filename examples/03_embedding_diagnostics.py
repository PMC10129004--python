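"""Supervised-UMAP silhouette profile of call-type structure.

A label-supervised 2-D embedding is repeated with fresh seeds; per-call
silhouettes in the embedding are averaged per class. Higher class means =
tighter, better-separated clusters under that labeling. Because supervision
shapes the layout, profiles are compared across labelings/feature sets
rather than against an absolute zero.
"""

import sungkit as sk

cfg = sk.SyntheticConfig(n_calls=250, seed=3)
corpus, _ = sk.generate_corpus(cfg)
table = sk.standardize(sk.build_feature_table(corpus, "dct"))

profile = sk.silhouette_profile(table, "call_type", n_reps=5, seed=0, n_neighbors=30)
print(f"overall mean silhouette (call types): {profile.overall_mean:.3f}")
print("per-class mean +- sd:")
for cls in profile.per_class_mean.index:
    print(f"  {cls:4s} {profile.per_class_mean[cls]:+.3f} "
          f"+- {profile.per_class_sd[cls]:.3f}")
print("\nclasses with low means sit in the graded overlap zone of the "
      "repertoire; their calls are the ones classifiers will confuse.")
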