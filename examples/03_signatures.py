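"""Extract rearrangement signatures and group patients by exposure.

The 32-channel catalogue combines SV type, size bin and clustering;
NMF with stability-based rank selection recovers the signatures, which
are then named by cosine match to a reference matrix, and patients are
grouped by consensus k-means on their exposure proportions.
"""

from svselect import consensus_group, extract_signatures, match_reference
from svselect.validation import planted_signature_catalogue

# a catalogue with three planted signatures and known truth
reference, catalogue = planted_signature_catalogue(seed=1, n_patients=60)

model = extract_signatures(catalogue, kmin=2, kmax=5, iters=500, replicates=10, seed=1)
print(f"stability-selected rank: k = {model.k}")
print(model.scores.round(3))

assignment = match_reference(model.W, reference)
print(assignment.round(3).to_string(index=False))

groups = consensus_group(model.H, Kmax=4, resamples=100, seed=1)
sizes = {}
for g in groups.labels.values():
    sizes[g] = sizes.get(g, 0) + 1
print(f"consensus patient groups: K = {groups.K}, sizes {sizes}")
print(
    "Cosines near 1 mean each extracted signature matches one planted "
    "profile; the groups partition patients by their dominant signature."
)
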