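"""Inactive-state populations from chemical-shift correlation slopes.

Builds a synthetic two-domain protein in fast exchange between an active and
an inactive conformation (inactive fractions 0.5 and 0.7 for the two
domains), then recovers those fractions from the slope of the
(apo - active_ref) vs (inactive_ref - active_ref) shift correlation.
"""

from confsel import build_correlation, fit_population
from confsel.synthetic import default_two_state_config, gen_two_state_tables

cfg = default_two_state_config(n_per_domain=30, p_a=0.5, p_b=0.7, seed=42)
tables = gen_two_state_tables(cfg)

for name, lo, hi, truth in (("CBD-A", 119, 243, 0.5), ("CBD-B", 269, 379, 0.7)):
    reporters = [r for r in cfg.endpoints if lo <= r <= hi]
    points = build_correlation(tables.apo, tables.active, tables.inactive,
                               reporters)
    fit = fit_population(points, seed=0)
    print(f"{name}: inactive fraction = {fit.slope:.3f} +/- {fit.slope_err:.3f}"
          f"  (r = {fit.r:.4f}, n = {fit.n} points, truth = {truth})")

print()
print("The slope of the through-origin fit is the molar fraction of the")
print("inactive conformation sampled by the apo state; r close to 1 confirms")
print("the two-state fast-exchange picture.")
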