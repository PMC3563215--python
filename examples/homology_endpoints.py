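"""The homology baseline: boundaries from alignment endpoints.

Alignment start/end positions from a domain-library search cluster at domain
termini. They are accumulated into a per-residue profile, smoothed by
repeated moving averaging, and peaks at least 60 residues from the termini
and from each other become boundaries.
"""

from domaincut import (
    assemble_endpoint_profile,
    predict_from_endpoints,
    smooth_by_averaging,
)
from domaincut.synthetic import generate_endpoint_samples

L, true_boundary = 300, 150
pairs = generate_endpoint_samples([true_boundary], L, n=200, jitter_sd=5.0, seed=5)
print(f"{len(pairs)} alignments; e.g. {pairs[:3]}")

profile = smooth_by_averaging(assemble_endpoint_profile(pairs, L), window=5, iterations=10)
prediction = predict_from_endpoints(profile, min_dist=60)
print(f"predicted domains: {prediction.to_chopping()} (true boundary at {true_boundary})")
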