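"""Soil aeration metrics for one sampling day.

Computes total porosity, WFPS and the relative gas diffusion
coefficient Dp/D0 from gravimetric water content and bulk density, for
a sandy loam wetted over a range of water contents.
"""

import numpy as np

from denitflux.soil import growing_degree_days, soil_state

rho_b = 1.35  # g cm-3, plough-layer bulk density
eps100 = 0.15  # m3 m-3, air content at -100 cm H2O

print("theta_g   WFPS    Dp/D0")
for theta_g in np.arange(0.10, 0.30, 0.04):
    st = soil_state(theta_g, rho_b, eps100)
    print(f"{theta_g:6.2f}  {st.wfps:6.2f}  {st.dp_d0:7.4f}")
# WFPS rises and Dp/D0 collapses as pores fill with water; values of
# Dp/D0 below ~0.02 indicate O2-limited conditions favouring
# denitrification and N2O release.

temps = [6.2, 8.0, 9.5, 4.1, 7.7, 11.3, 12.0]
print(f"\ngrowing degree days (base 0 C): {growing_degree_days(temps):.1f}")
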