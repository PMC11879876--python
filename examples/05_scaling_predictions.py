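"""Elasticity-exponent algebra: structure-based vs topology-based predictions.

Given the measured log-log slopes of the structural and topological
observables against volume fraction, the high-frequency elastic plateau
exponent is predicted two ways: from the mesh size (G'_p ~ N_minloop /
xi^3) and from the linking valence (G'_p ~ N_minloop <Z>). The geometric
overlap argument (<Z> ~ rho <l_min>^3) is evaluated alongside, plus the
classical phantom-network comparators.
"""

from nanolink.rheology import predict_scaling_exponents

# slopes (value, stderr) of each observable vs volume fraction rho
out = predict_scaling_exponents(
    n_minloop_slope=(1.0, 0.05),   # N_minloop ~ rho
    xi_slope=(-0.84, 0.03),        # mesh size above the overlap point
    z_slope=(1.4, 0.10),           # linking valence <Z> ~ rho^1.4
    lmin_slope=(0.1, 0.01),        # minimum-loop length, weak growth
)

mesh, mesh_err = out["mesh_exponent"]
link, link_err = out["link_exponent"]
geo, geo_err = out["geometric_z_exponent"]
print(f"mesh-based prediction:    G'_p ~ rho^{mesh:.2f} +- {mesh_err:.2f}")
print(f"linking-based prediction: G'_p ~ rho^{link:.2f} +- {link_err:.2f}")
print(f"geometric <Z> exponent:   <Z> ~ rho^{geo:.2f} +- {geo_err:.2f}")
print(f"phantom network:          G'_p ~ rho^{out['phantom_exponent']:.2f} "
      f"(prefactor (f-2)/f = {out['phantom_prefactor']:.2f})")
print(f"disordered phantom:       G'_p ~ "
      f"rho^{out['disordered_phantom_exponent']:.2f}")

print(
    "\nThe linking-based exponent (2.4) tracks a measured elasticity "
    "scaling of ~2.5 far better than the mesh-based one (3.5) or the "
    "phantom-network laws (1 and 1/3): above the overlap concentration "
    "the topology, not the pore size, sets the elasticity."
)
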