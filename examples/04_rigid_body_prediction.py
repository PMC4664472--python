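"""Rigid-body spectral densities from a rotational diffusion tensor.

Evaluates the Woessner spectral density for the backbone NH vectors of an
ideal helix tumbling as an axially symmetric rotor with a mild anisotropy
(D_par/D_perp = 1.4, typical of a compact two-domain protein), then shows
the shape-based ellipsoid estimator on an isotropic control.  The spread of
rigid-body J(0) across residues is the anisotropy artefact that must be
subtracted before calling internal dynamics.
"""

import numpy as np

from confsel import (
    DiffusionTensor,
    PhysicalConstants,
    estimate_tensor_ellipsoid,
    nh_vectors_from_structure,
    predict_J,
)
from confsel.synthetic import gen_toy_structure

tau_iso = 12e-9
ratio = 1.4
d_perp = 3.0 / (6 * tau_iso) / (2 + ratio)
# unique axis tilted from the helix axis, so NH orientations differ
tensor = DiffusionTensor.axial(ratio * d_perp, d_perp, axis=(0.5, 0.0, 0.866))
print(f"Tensor: D_par/D_perp = {ratio}, tau_iso = {tensor.tau_iso * 1e9:.1f} ns")

structure, _ = gen_toy_structure("helix", n_residues=30, seed=0)
k = PhysicalConstants()
omegas = [0.0, k.omega_n(700.13), k.omega_high(700.13)]
j0 = np.array([predict_J(tensor, nh, omegas)[0]
               for nh in nh_vectors_from_structure(structure)])
print(f"Rigid-body J(0) over {len(j0)} NH vectors: "
      f"{j0.mean() * 1e9:.2f} +/- {j0.std() * 1e9:.2f} x 1e-9 s/rad "
      f"(range {j0.min() * 1e9:.2f} - {j0.max() * 1e9:.2f})")

cloud, _ = gen_toy_structure("sphere_cloud", n_residues=3000, seed=1)
est = estimate_tensor_ellipsoid(cloud, tau_iso)
d_par_e, d_perp_e, _ = est.axial_components()
print(f"Ellipsoid estimate on an isotropic cloud: D_par/D_perp = "
      f"{d_par_e / d_perp_e:.3f} (expected 1)")
print()
print("Residues whose measured J(0) exceeds the rigid-body reference carry")
print("genuine ms-us dynamics; the reference absorbs tumbling anisotropy.")
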