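"""Shared helper for the example scripts: rarefy, SOM-type and label one group."""

from plankmap import (classify_samples, cluster_neurons, label_clusters, rarefy,
                      relative_abundance, subset_group, train_som)


def classify_group(dataset, group, seed=0, depth=17_000):
    rarefied, _ = rarefy(dataset.asv, depth=depth, seed=seed)
    samples = dataset.samples[dataset.samples["sample_id"].isin(rarefied.sample_ids)]
    sub, zero = subset_group(rarefied, dataset.taxonomy, group)
    sub = sub.select_samples([s for s in sub.sample_ids if s not in set(zero)])
    X = relative_abundance(sub).to_numpy().T
    model = train_som(X, grid=(6, 6), seed=seed)
    cluster_neurons(model, k=2)
    cls = classify_samples(model, X, sample_ids=sub.sample_ids, group=group)
    label_clusters(cls, samples, dataset.stations)
    return cls, samples
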