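"""Supervised apical/basal classification and structure importance.

Trains a 500-tree random forest (10 features tried per split) on the
cluster-derived apical/basal labels, reports the out-of-bag confusion
matrix and error, and ranks intracellular structures by mean decrease in
Gini impurity with a Tukey-Kramer comparison across replicates.
"""

from zygopolar import analyze_movies
from zygopolar.pipeline import movies_from_synthetic
from zygopolar.synthetic_data import SyntheticConfig, generate_arrays

cfg = SyntheticConfig(seed=1)
res = analyze_movies(
    movies_from_synthetic(generate_arrays(cfg)),
    probe_order=list(cfg.probes), seed=1,
)

rf = res.classification
print("OOB confusion matrix (rows true apical/basal, cols predicted):")
print(rf.confusion)
print(f"OOB error: {rf.oob_error_pct:.1f}%")

agg = rf.importance_by_structure.groupby("probe")["importance_pct"].mean()
letters = res.tukey.attrs["letters"]
print("\nmean decrease in Gini (%, averaged per replicate then per probe):")
for probe, val in agg.sort_values(ascending=False).items():
    print(f"  {probe:20s} {val:6.3f}  letter {letters[probe]}")
print("\nProbes sharing a letter are not significantly different "
      "(Tukey-Kramer, p < 0.01); the planted boundary signal lives in the "
      "vacuolar template, which should rank first.")
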