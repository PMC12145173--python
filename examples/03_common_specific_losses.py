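"""The two fingerprint-space losses on hand-checkable toy inputs.

Lc (alignment) is the summed squared distance of the four common-space
encodings to their mean; Ls (decorrelation) is the squared Frobenius
distance of their 4x4 Gram matrix from the identity.
"""

import numpy as np

from moafuse.fp_cs import common_feature, common_loss, common_target, specific_loss

quad = (
    np.array([2.0, 0.0]),
    np.array([0.0, 2.0]),
    np.array([0.0, 0.0]),
    np.array([2.0, 2.0]),
)
print("common target (mean):", common_target(quad).data)  # (1, 1)
print("common loss Lc:      ", common_loss(quad).item())  # 8.0
print("common feature (sum):", common_feature(quad).data)  # (4, 4)

eye = tuple(np.eye(4))
print("Ls, orthonormal rows:", specific_loss(eye).item())  # 0.0
row = np.array([1.0, 0.0, 0.0, 0.0])
print("Ls, 4 identical unit rows:", specific_loss((row, row, row, row)).item())  # 12.0
print("Ls, rows = 2*I:", specific_loss(tuple(2.0 * np.eye(4))).item())  # 36.0
# Minimizing Lc pulls the four views together; minimizing Ls pushes the
# specific encodings toward mutual orthogonality at unit norm.
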