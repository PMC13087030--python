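"""Score motifs for CpG content, promoter preference and pioneer-factor makeup."""

import numpy as np

from chromodyn.motifs import (MotifOccurrence, PWM, cpg_score, has_cpg,
                              pe_score, ptf_tally)

uniform = PWM("uniform", np.ones((4, 2)))
perfect_cg = PWM("perfect_cg", np.array([[0, 0], [1, 0], [0, 1], [0, 0]], float))
for pwm in (uniform, perfect_cg):
    print(f"{pwm.name:<12} CpG score {cpg_score(pwm):5.2f}  "
          f"CpG-containing: {has_cpg(pwm)}")
# scores > 6 mark motifs carrying a genuine CpG dinucleotide

occurrences = (
    [MotifOccurrence("KLF4", "chr1", 1000 * i, 1000 * i + 10, context="promoter")
     for i in range(3)]
    + [MotifOccurrence("KLF4", "chr2", 5000, 5010, context="enhancer")])
print(f"KLF4 P/E score: {pe_score(occurrences):.2f}  "
      f"(3 promoter / 1 enhancer occurrences)")

tally = ptf_tally(up_motifs={"NANOG", "OCT4", "KLF4", "GATA3"},
                  down_motifs={"YY1", "NFYA", "REST", "CTCF"},
                  ptf_list={"NANOG", "OCT4", "GATA3", "FOXA1"})
print(f"pioneer TFs among up-motifs {tally.up_proportion:.2f}, "
      f"down-motifs {tally.down_proportion:.2f}, "
      f"exact two-sided p = {tally.p_value:.3f}")
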