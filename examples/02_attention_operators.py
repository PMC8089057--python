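"""The two attention operators on small inputs.

Sequence attention: multi-head scaled dot-product attention over residues,
Z = softmax(Q K^T / sqrt(d_att)) V per head. Regional attention: each map
cell attends over its n x n surrounding window (masked softmax at borders).
"""

import numpy as np

from contactattn.attention import (
    init_attention1d_params, init_regional_attention_params,
    multihead_attention_1d, region_stretch, regional_attention,
)
from contactattn.interpretation import regional_score_map, sequence_importance

rng = np.random.default_rng(0)
L = 10

# --- sequence attention ----------------------------------------------------
params = init_attention1d_params(d_in=8, n_heads=4, d_att=4, rng=rng)
x = rng.normal(size=(L, 8))
z, weights = multihead_attention_1d(x, params)
print(f"sequence attention: input (L={L}, 8) -> Z {z.shape}, "
      f"weights {weights.w_att.shape}")
print("  every attention row sums to 1:",
      np.allclose(weights.w_att.sum(axis=-1), 1.0))
imp = sequence_importance(weights)
print(f"  residue importance (column sums, total = L): sum = {imp.sum():.3f}")

# --- region stretching and regional attention -------------------------------
f = rng.normal(size=(L, L, 6))
stretched, inbounds = region_stretch(f, n=5)
print(f"\nregion stretch: map (L, L, 6) -> {stretched.shape} "
      f"(25 = flattened 5x5 window, row-major)")
print(f"  corner cell has {int(inbounds[0, 0].sum())} in-bounds window cells,"
      f" interior cells {int(inbounds[5, 5].sum())}")

rparams = init_regional_attention_params(channels=6, n_heads=4, d=4,
                                         c_out=6, n=5, rng=rng)
out, rweights = regional_attention(f, rparams)
print(f"regional attention: output {out.shape}, "
      f"window weights {rweights.weights.shape}")
received = regional_score_map(rweights)
print(f"  received-attention mass = {received.sum():.1f} (= L^2 = {L * L}: "
      "each cell distributes exactly one unit)")
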