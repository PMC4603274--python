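"""Scattering-length densities, contrast and the concentration chain.

Computes the X-ray SLD of silica and water at the Cu K-alpha energy, their
contrast (the 'eta' parameter of a sphere model), and converts a fitted
distribution scale N into number/molar concentration and mass fraction.
"""

import sasmodelfit as sm
from sasmodelfit.distributions import SizeDistribution
from sasmodelfit.physprops import concentration_report

silica = sm.xray_sld(sm.MaterialSpec("SiO2", density=2.29, energy=8.042))
water = sm.xray_sld(sm.MaterialSpec("H2O", density=1.0, energy=8.042))
print(f"SLD(SiO2)  = {silica:.4g} cm^-2")
print(f"SLD(water) = {water:.4g} cm^-2")
print(f"contrast   = {sm.contrast(silica, water):.4g} cm^-2")
print()

# gold dispersion: fitted N in (cm^-1, nm^-1, cm^-2) units, Gaussian radius
# distribution X0 = 4.48 nm, s = 0.44 nm, bulk gold density 19.30 g/cm^3
dist = SizeDistribution("gaussian", N=7.68e-30, X0=4.48, s=0.44)
rep = concentration_report(7.68e-30, dist, particle_density=19.30)
print(f"number concentration = {rep.number_conc:.4g} cm^-3")
print(f"molar concentration  = {rep.molar_conc:.4g} mol/l")
print(f"volume fraction      = {rep.volume_fraction:.4g}")
print(f"mass fraction        = {rep.mass_fraction * 1e6:.4g} ug per g of water")
print()
print("The mass fraction is the double check on an absolute-intensity fit:")
print("it must agree with what is known about the sample preparation.")
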