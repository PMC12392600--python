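"""PCA of a small hand-written pedigree, checked against the dense matrix.

Builds a 9-individual pedigree, computes inbreeding, the sparse factor
L^-1 of the precision matrix, and the leading principal components of the
relationship matrix A without ever forming A — then prints the summary
table.  On a pedigree this small the dense tabular-method matrix is also
printed so the numbers can be verified by eye.
"""

import numpy as np

from pedpca import (
    ImplicitOperator,
    Pedigree,
    RsvdConfig,
    build_precision_cholesky,
    dense_A_oracle,
    inbreeding,
    rsvd_pca,
    summarise,
    trace_exact,
)

# founders 1-3; 4 = 1x2, 5 = 1x3, 6 = 4x5 (inbred), 7-9 further matings
ped = Pedigree.from_indices(
    sire=[0, 0, 0, 1, 1, 4, 4, 6, 6],
    dam=[0, 0, 0, 2, 3, 5, 5, 7, 7],
)

F = inbreeding(ped)
print("inbreeding coefficients:", np.round(F, 4))
# individual 6's parents are half sibs sharing parent 1 -> F = A(4,5)/2 = 0.125

chol = build_precision_cholesky(ped, F)
print(f"\nL^-1: {chol.n} x {chol.n} with {chol.nnz} non-zeros (<= 3n = {3 * chol.n})")

op = ImplicitOperator(chol, centred=False)
res = rsvd_pca(op, RsvdConfig(k=9, l=9, seed=0), total_variance=trace_exact(F))
print("\n" + summarise(res))

A = dense_A_oracle(ped)
print("\ndense relationship matrix (oracle, for comparison):")
print(np.round(A, 3))
print("sum of squared sdev at full sketch equals Tr(A) =", np.trace(A))
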