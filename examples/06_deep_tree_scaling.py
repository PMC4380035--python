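"""Numerical scaling on a deep tree.

Per-site likelihoods shrink exponentially with tree depth; on a 700-taxon
chain the raw products leave the double-precision range entirely.  The
engine rescales a pattern's CLV by 2^256 whenever its maximum drops below
2^-256 and adds the log-scalers back at the root, so the scaled modes
return identical finite values where the unscaled mode underflows.
"""

from phylokit import (PartitionModel, SimulationSpec, TreeLikelihood,
                      compress_patterns, simulate_alignment)
from phylokit.likelihood import UnderflowError
from phylokit.tree import Tree

n = 700
names = [f"s{i}" for i in range(n)]
tree = Tree()
base = tree.new_inner()
tree.connect(base, tree.new_tip(names[0]), 0.3)
tree.connect(base.nxt, tree.new_tip(names[1]), 0.3)
prev = base.nxt.nxt
for nm in names[2:-1]:
    mid = tree.new_inner()
    tree.connect(prev, mid, 0.3)
    tree.connect(mid.nxt, tree.new_tip(nm), 0.3)
    prev = mid.nxt.nxt
tree.connect(prev, tree.new_tip(names[-1]), 0.3)

m = PartitionModel.from_spec("JC")
sim = simulate_alignment(SimulationSpec(tree, [m], [6], seed=1))
paln = compress_patterns(sim.alignment, sim.scheme)

for mode in ("per-site", "per-node"):
    res = TreeLikelihood(tree, paln, scaling=mode).evaluate(min(tree.edges))
    print(f"scaling={mode:9s}: logL = {res.total:.6f} "
          f"({res.scaling_events} scaling events)")
try:
    TreeLikelihood(tree, paln, scaling="none").evaluate(min(tree.edges))
except UnderflowError as e:
    print(f"scaling=none     : underflow, as expected -> {e}")
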