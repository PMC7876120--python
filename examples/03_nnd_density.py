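"""Nearest-neighbor statistics and molecular density of a random field.

Generates a homogeneous Poisson field at 600 molecules/µm² (the
extrapolated in-adhesion density scale), fits the first-, third- and
fifth-neighbor distance distributions with the 2D Poisson law
P_k(r) = 2 (pi rho)^k r^(2k-1) exp(-pi rho r^2) / (k-1)!, and measures
the density inside a region mask.
"""

from qsmcl import (RegionMask, density_in_mask, fit_poisson_nnd,
                   gen_random_field, mean_nnd_poisson, nnd)

roi = RegionMask.rectangle(10_000.0, 10_000.0)  # 10 x 10 µm
field = gen_random_field(600.0, roi, seed=3)
print(f"{len(field)} molecules at 600/µm²")

result = nnd(field.points)
print(f"mean NND: {result.mean:.2f} nm "
      f"(closed form 0.5/sqrt(rho) = {mean_nnd_poisson(600.0):.2f} nm)")

for k in (1, 3, 5):
    fit = fit_poisson_nnd(nnd(field.points, k=k))
    print(f"order-{k} fit: rho = {fit.density_um2:.0f}/µm² "
          f"(CI {fit.ci_um2[0]:.0f}-{fit.ci_um2[1]:.0f}), "
          f"GOF p = {fit.gof_pvalue:.2f}")

mask = RegionMask.rectangle(2_000.0, 2_000.0, label="FA")
print(f"density in 4 µm² mask: {density_in_mask(field.points, mask):.0f}/µm²")
print("-> consistent order-k fits indicate a spatially random organization")
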