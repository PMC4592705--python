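"""Center-of-mass shifts under r-protein deletions (mass-balance analysis).

Generates a balanced assembly — an RNA-like core with L9-like and L12-like
protein appendages on opposite sides — and reports how deleting each
appendage, or both, moves the center of mass relative to the PTC stand-in.
"""

from ribomech import coarse_grain
from ribomech.mass import DeletionSpec, cm_shift_report
from ribomech.synthetic import (
    FixtureSpec,
    component_selections,
    make_balanced_assembly,
    ptc_selection_of,
)

structure, gt = make_balanced_assembly(FixtureSpec(seed=5))
nodes = coarse_grain(structure, component_selections(gt))
variants = [
    DeletionSpec("delta_L9", ("L9",)),
    DeletionSpec("delta_L12", ("L12",)),
    DeletionSpec("delta_both", ("L9", "L12")),
]
report = cm_shift_report(nodes, variants, ptc_selection_of(gt))
print(report.to_frame().to_string(index=False))
print(
    "\nEach single deletion moves the CM several Å away from the removed"
    " appendage\n(direction_dot < 0); deleting both opposite appendages"
    " largely cancels, leaving\na much smaller shift — the compensation that"
    " makes L9 a counterweight to the\nL12 stalk."
)
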