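"""The equivariant branch is blind to rigid motions of the input structure.

Rotating and translating the protein's coordinates leaves per-residue
embeddings unchanged (invariance) while the internal coordinate trajectory
rotates along (equivariance) — the property that lets one model apply to
arbitrarily oriented structures.
"""

import numpy as np

from egpdi import EgnnConfig, EgnnEncoder
from egpdi.structure import build_adjacency, compute_edge_features, edges_from_adjacency

rng = np.random.default_rng(1)
coords = rng.normal(scale=4.0, size=(12, 3))
A = build_adjacency(coords, cutoff=8.0)
ei = edges_from_adjacency(A)
E = compute_edge_features(coords, ei, orientations=rng.normal(size=(12, 3)))
X = rng.normal(size=(12, 16))

encoder = EgnnEncoder(EgnnConfig(n_layers=2, hidden_dim=8, mlp_width=6,
                                 input_dim=16), rng)
h_ref, trace_ref = encoder.forward(X, A, coords, ei, E, return_coords=True)

# a random rotation + translation
Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
Q = Q * np.sign(np.diag(R))
t = rng.normal(scale=10.0, size=3)
h_rot, trace_rot = encoder.forward(X, A, coords @ Q.T + t, ei, E,
                                   return_coords=True)

emb_err = np.abs(h_rot.data - h_ref.data).max()
coord_err = max(np.abs(xr - (x @ Q.T + t)).max()
                for xr, x in zip(trace_rot, trace_ref))
print(f"max embedding change under rigid motion:  {emb_err:.2e}  (invariant)")
print(f"max coordinate deviation from R x + t:    {coord_err:.2e}  (equivariant)")
print("both are at floating-point noise level: the encoder sees only geometry,"
      " not the frame")
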