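"""Domain definitions and residue-class censuses of the lipid-export pathway.

Prints the gateway (the 29-residue charged loop), the annulus (tunnel-lining
residues within 10 Å of the gateway), their 53-residue union, and the
basic/acidic split of the 11 charged gateway residues.
"""

from lipidgate import (
    ANNULUS,
    CHARGED_GATEWAY,
    GATEWAY,
    census,
    union_size,
)
from lipidgate.domains import CHARGED_GATEWAY_CODES, ORIFICE_FIG1, ORIFICE_RESULTS

print(f"gateway residues          : {len(GATEWAY)} (564-592)")
print(f"annulus residues          : {len(ANNULUS)} (69, 71-80, 363, 368-379)")
print(f"gateway ∪ annulus         : {union_size(GATEWAY, ANNULUS)} residues")
print(f"orifice presets           : {sorted(r for _, r in ORIFICE_FIG1.members)} "
      f"or {sorted(r for _, r in ORIFICE_RESULTS.members)}")

counts = census(CHARGED_GATEWAY, CHARGED_GATEWAY_CODES)
print(f"charged gateway residues  : {len(CHARGED_GATEWAY)} "
      f"({counts['basic']} basic, {counts['acidic']} acidic)")
# These counts are pure set arithmetic on the published residue lists; they
# are the fixed inputs every structural analysis below builds on.
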