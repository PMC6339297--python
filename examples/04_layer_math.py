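"""Reference layer math: convolution, LRN, pooling, and atrous receptive fields.

Shows the exact numerical contracts of the segmentation-network primitives,
including the equivalence of dilated convolution with its zero-inserted
kernel and the receptive-field arithmetic that motivates it.
"""

import numpy as np

from gridpick import netmath

rng = np.random.default_rng(0)
x = rng.standard_normal((2, 8, 8))   # 2 channels, 8x8
w = rng.standard_normal((2, 3, 3))   # matching 3x3 kernel

y = netmath.conv2d(x, w)
print(f"valid convolution : {x.shape} * {w.shape} -> {y.shape}")

act = netmath.relu(y)
print(f"relu              : {np.sum(y < 0)} negatives clamped to 0")

norm = netmath.local_response_norm(x, netmath.LRNParams(a=1e-4, b=0.75, size=2))
print(f"LRN               : max |out|/|in| = "
      f"{np.max(np.abs(norm) / np.abs(x)):.6f} (never amplifies)")

pooled = netmath.max_pool(y, window=2, stride=2)
print(f"max pool 2x2      : {y.shape} -> {pooled.shape}")

for rate in (1, 2, 4):
    fov = netmath.effective_field_of_view(3, rate)
    big = netmath.zero_inserted_kernel(w, rate)
    xa = rng.standard_normal((2, fov + 4, fov + 4))
    err = np.abs(netmath.atrous_conv2d(xa, w, rate) - netmath.conv2d(xa, big)).max()
    print(f"atrous rate {rate}     : field of view {fov}x{fov}, "
          f"{netmath.kernel_parameter_count(3)} parameters, "
          f"zero-insertion equivalence error {err:.2e}")

# A 3x3 kernel at rate 2 sees a 5x5 neighborhood with only 9 parameters;
# the dilated and zero-inserted formulations agree to machine precision.
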