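"""Signature IV: parallel divergence of haplotype subtrees.

Among resolved per-region trees that separate all A from all B haplotypes,
count those whose two rooted subtrees match, and test the excess over the
uniform-topology null x = 1/#rooted-topologies with an exact binomial tail.
Shown here with the published counts for the two clonal lineages.
"""

from fractions import Fraction

from meselson import binomial_tail, n_rooted_topologies
from meselson import ref_tables as rt

for lineage, (n_sep, n_match, k) in rt.PARALLEL_DIVERGENCE_COUNTS.items():
    x = Fraction(1, n_rooted_topologies(k))
    p = binomial_tail(n_sep, n_match, x)
    fold = n_match / (n_sep * float(x))
    print(
        f"lineage {lineage}: {n_match}/{n_sep} separating trees match "
        f"(k = {k} taxa per subtree, x = {float(x):.3f}); "
        f"{fold:.1f}x the chance expectation, P = {p:.2e}"
    )
# Both lineages show matching far above chance (P < 0.001): the haplotype
# subtrees co-diverged through the same population history, which neither a
# hybrid origin nor paralogy can produce.
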