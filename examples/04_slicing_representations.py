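"""The five input representations derived from one 3D sample.

Every representation except the mean projection is a lossless permutation
of the voxels; the printed shapes are the model input sizes at full scale.
"""

import numpy as np

from triplanar import (
    flatten_for_svm,
    to_axial_stack,
    to_mean_value_2d,
    to_sequence_1d,
    to_triplanar,
)
from triplanar.slicing import reconstruct_from_stack

volume = np.random.default_rng(0).standard_normal((91, 109, 91))

tri = to_triplanar(volume)
print("tri-planar stacks (H, W, C):", [s.shape for s in tri])
print("reconstruction exact:",
      all(np.array_equal(reconstruct_from_stack(s), volume) for s in tri))

print("axial multichannel 2D:", to_axial_stack(volume).shape)
print("mean-value 2D:", to_mean_value_2d(volume).shape)

seq = to_sequence_1d(volume)
print(f"1D sequence: {seq.shape} (length dimY*dimZ = {109 * 91}, dimX features)")

flat = flatten_for_svm(volume)
print(f"flattened vector for PCA+SVM: {flat.shape} (= 91*109*91 voxels)")
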