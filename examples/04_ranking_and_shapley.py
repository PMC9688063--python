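"""Rank the 20 features by chi-square importance and explain a prediction.

Importance is -log10 of the Pearson chi-square p-value on equal-frequency
bins versus group. A logistic model on the top features is then explained
at one epoch with exact interventional Shapley values, which sum to the
score's deviation from the background average.
"""

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

import eegms
from eegms.stats import shapley_values

cfg = eegms.GeneratorConfig(n_per_group=4, duration=60.0, seed=2)
cohort = eegms.generate_cohort(cfg)
epoch_sets = [eegms.preprocess(rec) for rec, _ in cohort]
pooled = eegms.concatenate_peaks([
    eegms.extract_peak_maps(ep)
    for es in epoch_sets for ep in es.retained_epochs()
])
ts, _ = eegms.modified_kmeans(pooled, seed=0)
ts = eegms.assign_canonical_labels(ts, eegms.make_templates(cfg.montage))
table, _ = eegms.extract_feature_table(epoch_sets, ts)

ranking = eegms.chi2_rank_features(table)
print("top-6 features by chi-square importance (-log10 p):")
for name, score in zip(ranking.names[:6], ranking.scores[:6]):
    print(f"  {name:14s} {score:6.1f}")

top = ranking.top(6)
x = StandardScaler().fit_transform(table[top].to_numpy())
y = (table.group == "SZ").astype(int).to_numpy()
model = LogisticRegression().fit(x, y)

def score(v):
    return model.decision_function(np.asarray(v))

query = x[0]
phi = shapley_values(score, query, x)
print(f"\nShapley explanation of epoch 0 ({table.group.iloc[0]}):")
for name, p in zip(top, phi):
    print(f"  {name:14s} {p:+.3f}")
total = score(query[None])[0] - score(x).mean()
print(f"  sum = {phi.sum():+.3f}  (score deviation from average: {total:+.3f})")
# negative contributions push the prediction toward HC, positive toward SZ.
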