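"""Calibrating the power-law g-ratio against histology.

The peripheral-nervous-system reference curve is
g_REF(r) = 0.22*log10(2r) + 0.508.  Central-nervous-system axons have
higher g-ratios; anchoring g = 0.7 at r = 0.9 um gives the additive
offset.  Fitting beta*r^alpha to each curve yields the constants used
when the power law is held fixed during estimation.
"""

from axonmorph import ReferenceGRatioCurve, cns_offset, fit_power_law

offset = cns_offset(target_g=0.7, r_ref=0.9)
print(f"CNS offset: {offset:.3f}  (rounds to 0.14)")

pns = fit_power_law(ReferenceGRatioCurve())
cns = fit_power_law(ReferenceGRatioCurve().with_cns_offset())
print(f"peripheral fit: alpha = {pns.alpha:.3f}, beta = {pns.beta:.3f}, R2 = {pns.r_squared:.3f}")
print(f"CNS fit:        alpha = {cns.alpha:.3f}, beta = {cns.beta:.3f}, R2 = {cns.r_squared:.3f}")

# The CNS pair (0.14, 0.71) is what the estimation module fixes alpha
# and beta to when inverting for the radius-distribution parameters.
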