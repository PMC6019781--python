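"""Profile cis-element divergence between species that still edit a site
and species whose genome hard-codes the edited T."""

import numpy as np

from chloroedit import (
    SpeciesCisElement,
    partition_by_genomic_state,
    position_profile,
    translate_window,
)

span = (-20, 4)
width = span[1] - span[0] + 1
zero = -span[0]
rng = np.random.default_rng(0)

consensus = list("ACGT" * 7)[:width]
consensus[zero] = "C"  # the edited cytidine

elements = []
for i in range(6):  # species that still require editing: conserved window
    elements.append(SpeciesCisElement(f"editing_sp{i}", "".join(consensus), span=span))
for i in range(4):  # editing lost: T at position 0, divergence upstream
    w = list(consensus)
    w[zero] = "T"
    for pos in (-7, -15, -17, -18, -20):
        idx = pos - span[0]
        w[idx] = [x for x in "ACGT" if x != consensus[idx]][int(rng.integers(3))]
    elements.append(SpeciesCisElement(f"lost_sp{i}", "".join(w), span=span))

c_group, t_group, other = partition_by_genomic_state(elements)
print(f"groups: {len(c_group)} editing-required, {len(t_group)} editing-lost")

profile = position_profile(c_group, t_group)
print("highlighted positions (new nucleotides in one group):",
      profile.highlighted_positions())
# Positions upstream of the lost site are free to diverge once factor
# recognition is no longer needed; conserved positions are 'faded'.

print("pre-editing codon CCA ->", translate_window("CCA"))
print("edited codon     CUA ->", translate_window("CUA"))
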