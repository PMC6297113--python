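"""Choose the number of biclusters by bi-cross-validation.

Holds out row x column blocks of the 50 x 250 benchmark matrix, refits NMF
on the retained submatrix at each candidate rank, reconstructs the held-out
block through the fitted low-rank map, and accumulates the residuals.  The
rank minimizing the accumulated residual (smallest on numerical ties) is
the data-driven estimate of the number of biclusters.
"""

import mfbiclust as mb

ds = mb.generate_benchmark_dataset1(seed=0)  # truth has 3 biclusters
result = mb.select_rank(ds.matrix, candidate_ranks=list(range(1, 9)), seed=0)

print(result.table().to_string(index=False, float_format=lambda v: f"{v:12.1f}"))
print(f"selected rank: {result.selected_k} (planted: {ds.truth.k})")
# The residual drops sharply until the true rank is reached (each extra
# factor explains one planted bicluster) and flattens or rises beyond it
# (extra factors only chase noise, which does not generalize to the
# held-out block).
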