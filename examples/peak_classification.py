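"""Classify peaks from a planted genomic fixture and recover every label."""

import collections

import numpy as np

from chromodyn.chromatin import (classify_differential, classify_h2az_levels,
                                 rescued_peaks, spike_in_factors,
                                 turnover_groups)
from chromodyn.fixtures import make_genomic_fixture

fx = make_genomic_fixture(n_peaks=300, seed=42)
print("spike-in factors:", spike_in_factors(fx.spike_counts))

peaks = fx.peaks
diff = classify_differential(peaks["wt_ctrl"], peaks["wt_iaa"], "histone")
print("differential classes:", dict(collections.Counter(diff)))
print("matches planted truth:",
      bool(np.all(diff == fx.truth["differential"])))

resc = rescued_peaks(peaks["wt_ctrl"], peaks["wt_iaa"],
                     peaks["cd_ctrl"], peaks["cd_iaa"])
print(f"rescued peaks: {int(resc.sum())} "
      f"(planted {int(fx.truth['rescued'].sum())})")

groups = turnover_groups(fx.turnover[[f"t{t}h" for t in (0, 2, 4, 6, 8)]])
print("turnover groups:", dict(collections.Counter(groups)))
# ~72 % of peaks lose most of their signal within 2 h of depletion

levels = classify_h2az_levels(np.random.default_rng(0).uniform(0, 50, 100))
print("H2A.Z level classes (100 nucleosomes):",
      dict(collections.Counter(levels)))
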