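"""Marginal ancestral states, and ascertainment-corrected likelihood for
variable-sites-only (SNP-like) data.

The ancestral posterior at an inner node multiplies the three directional
subtree likelihoods with the stationary frequencies.  The ascertainment
correction divides each site likelihood by Pr(site is variable), undoing
the bias of datasets from which constant sites were removed.
"""

from phylokit import (TreeLikelihood, compress_patterns, default_scheme,
                      parse_fasta, parse_newick)
from phylokit.alignment import parse_partition_file

FASTA = """>a
ACGGA
>b
ACGTA
>c
GCGTC
>d
GTGTC
"""
aln = parse_fasta(FASTA)
tree = parse_newick("((a:0.1,b:0.1):0.15,c:0.1,d:0.1);")

paln = compress_patterns(aln, default_scheme(aln, "JC"))
tl = TreeLikelihood(tree, paln)
node = tree.tips["a"].back.node_id
post = tl.ancestral_states(node)
print("posterior state probabilities at the (a,b) ancestor:")
for p, col in enumerate(paln.parts[0].patterns):
    probs = ", ".join(f"{s}:{v:.2f}" for s, v in zip("ACGT", post[p]))
    print(f"  pattern {col}: {probs}")

# the same data treated as variable-sites-only (note: no constant columns)
var_only = parse_fasta(">a\nAGA\n>b\nATA\n>c\nGTC\n>d\nGTC\n")
scheme = parse_partition_file("JC+ASC, p1 = 1-3", 3)
tl2 = TreeLikelihood(tree, compress_patterns(var_only, scheme))
res = tl2.evaluate(min(tree.edges))
print(f"\nascertainment-corrected logL: {res.total:.4f}")
print(f"Pr(a site is constant) on this tree: {res.asc_probs[0]:.4f}"
      " (each site's likelihood is divided by 1 minus this)")
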