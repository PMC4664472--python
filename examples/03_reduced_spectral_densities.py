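"""Reduced spectral density mapping of 15N relaxation.

Simulates model-free R1/R2/NOE data for the full construct at 700.13 MHz
(tau_c = 18 ns, S^2 = 0.85) with exchange broadening Rex = 3 s^-1 confined
to the CBD-A hinge helices, maps the rates into J(0), J(wN) and J(0.87wH),
and averages over the conserved sub-regions.  Elevated J(0) in the hinge —
and only there — is the signature of ms-us dynamics surviving cAMP binding.
"""

from confsel import PhysicalConstants, default_domains, reduce_map, region_average
from confsel.synthetic import default_relaxation_config, gen_relaxation

k = PhysicalConstants()
cfg = default_relaxation_config(tau_c_ns=18.0, hinge_rex=3.0, seed=7)
fixture = gen_relaxation(cfg, k)
densities = [reduce_map(rec, k) for rec in fixture.records]

domains = default_domains()
print("J(0) x 1e9 s/rad, CBD-A regions (hinge carries the Rex load):")
for region in ("N3A", "beta2-3", "BBR", "PBC", "hinge", "Total"):
    avg = region_average(densities, domains["CBD-A"], region)
    print(f"  {region:8s} {avg.j0_mean * 1e9:5.2f} +/- {avg.j0_sd * 1e9:4.2f}"
          f"  (n = {avg.n})")

d2 = k.d**2
c2 = k.c(cfg.field_MHz) ** 2
print()
print(f"Expected hinge elevation from Rex = 3 s^-1: "
      f"{3.0 / (d2 / 2 + 2 * c2 / 3) * 1e9:.2f} x 1e-9 s/rad")
print("Because no exchange term is subtracted from R2, conformational")
print("exchange shows up as exactly this J(0) excess.")
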