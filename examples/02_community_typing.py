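"""Type one group's communities with a 6x6 self-organizing map.

Trains the Kohonen map on within-group relative abundances, cuts the neurons
into the two most distinct clusters (Ward linkage), names them nearshore /
offshore by which cluster's occurrence-weighted station centroid lies closer
to the coast, and screens for the ASVs with the strongest differential
abundance between the two types.
"""

import numpy as np

from plankmap import (SimConfig, classify_samples, cluster_neurons,
                      differential_abundance, label_clusters, rarefy,
                      relative_abundance, simulate_dataset, subset_group,
                      train_som)

dataset = simulate_dataset(SimConfig(), seed=1)
rarefied, report = rarefy(dataset.asv, depth=17_000, seed=0)
samples = dataset.samples[dataset.samples["sample_id"].isin(rarefied.sample_ids)]
print(f"rarefied to 17,000 reads: {len(report.kept)} kept, "
      f"{len(report.dropped)} dropped")

group = "cyanobacteria"
sub, zero = subset_group(rarefied, dataset.taxonomy, group)
sub = sub.select_samples([s for s in sub.sample_ids if s not in set(zero)])
X = relative_abundance(sub).to_numpy().T

model = train_som(X, grid=(6, 6), seed=0)
cluster_neurons(model, k=2)
cls = classify_samples(model, X, sample_ids=sub.sample_ids, group=group)
geo = label_clusters(cls, samples, dataset.stations)
model.cluster_labels = dict(zip(geo["cluster"], geo["label"]))

print(f"SOM quantization error: {model.quantization_errors[-1]:.4f} "
      f"(epoch 1: {model.quantization_errors[0]:.4f})")
print(geo[["cluster", "label", "centroid_distance_km"]].round(1).to_string(index=False))

truth = dataset.truths.set_index("sample_id")["true_label"]
acc = np.mean(cls["label"].to_numpy() == truth.loc[cls["sample_id"]].to_numpy())
print(f"agreement with the generator's true community type: {acc:.1%}")

da = differential_abundance(sub, cls)
print("ASVs past the 99th-percentile differential-abundance cut:",
      ", ".join(da.loc[da["flagged"], "asv_id"]))
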