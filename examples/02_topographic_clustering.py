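"""Topographic clustering and map-count selection on planted data.

Builds a noisy topography series that alternates between two prototype
maps, clusters it with AAHC, and shows how the fraction of explained
variance (GEV) grows with the number of templates until the 90% rule
picks the planted count.
"""

import numpy as np

from evtopo import aahc_cluster, select_n_maps, spatial_correlation
from evtopo.containers import average_reference

rng = np.random.default_rng(3)
protos = average_reference(rng.standard_normal((2, 32)), axis=1)
protos /= np.linalg.norm(protos, axis=1, keepdims=True)
labels_true = np.tile([0, 0, 0, 1, 1, 1], 10)
strength = 1.0 + np.abs(rng.standard_normal(labels_true.size))
series = strength[:, None] * protos[labels_true]
series += 0.05 * rng.standard_normal(series.shape)
series = average_reference(series, axis=1)

hierarchy = aahc_cluster(series, range(1, 7))
q_star, kl = select_n_maps(hierarchy, gev_threshold=0.90)

print("q    GEV")
for q in sorted(hierarchy):
    marker = " <- selected (first q with GEV >= 0.90)" if q == q_star else ""
    print(f"{q}    {hierarchy[q].gev_total:.3f}{marker}")

best = hierarchy[q_star]
for k, proto in enumerate(protos):
    r = max(abs(spatial_correlation(proto, m)) for m in best.maps)
    print(f"planted map {k}: best |spatial correlation| with a template = {r:.3f}")
# Both planted maps are recovered almost exactly (correlation ~ 1); the
# GEV jump from q=1 to q=2 reflects the genuine two-map structure, and
# further templates only absorb noise.
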