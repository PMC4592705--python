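"""PTC rigidity from experimental and from ANM-predicted B-factors.

On a fixture with a planted low-B island at the core center (the PTC
stand-in), the summary shows the PTC sitting deep in the rigid tail of the
B-factor distribution — and the ANM prediction, which knows nothing about
the planted values, recovers the same verdict from contact topology alone.
"""

from ribomech import ENMParameters, build_hessian, coarse_grain, compute_modes, mode_fluctuations
from ribomech.mass import ptc_rigidity_summary
from ribomech.synthetic import (
    FixtureSpec,
    component_selections,
    make_balanced_assembly,
    ptc_selection_of,
)

structure, gt = make_balanced_assembly(FixtureSpec(seed=5))
nodes = coarse_grain(structure, component_selections(gt))
ptc = ptc_selection_of(gt)

exp = ptc_rigidity_summary(nodes, ptc, source="experimental")
print("experimental B-factors:", exp.to_dict())

params = ENMParameters()
modes = compute_modes(build_hessian(nodes.positions, params))
_, b_pred = mode_fluctuations(modes, params)
pred = ptc_rigidity_summary(nodes, ptc, source="predicted", bfactors=b_pred)
print("ANM-predicted B-factors:", pred.to_dict())
print(
    "\nBoth rank the PTC nodes far below the 50th percentile: the catalytic"
    " center\nsits in a rigid, well-buried region, whether rigidity is read"
    " from the\ncrystallographic B column or from network topology."
)
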