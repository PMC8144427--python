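"""Sample individual 25OHD trajectories under the three schemes.

Draws one participant from a deficient population (annual mean 35 nmol/L)
and prints their status at the seasonal trough (March 1) and peak
(September 1) without supplementation, under a fixed 20 nmol/L-equivalent
daily dose, and under concentration control holding status above a
personal ~50 nmol/L target.
"""

import numpy as np

import vitdpower as vp

pop = vp.PopulationStatusSpec(mu_baseline=35.0, sigma_H=5.0, mu_A=15.0, sigma_A=5.0)
fixed = vp.FixedDoseSpec(dose_equiv=20.0, mu_omega=0.8, sigma_omega=0.1)
rcct = vp.ConcentrationControlSpec(mu_rho=50.0, sigma_rho=5.0)

rng = np.random.default_rng(1)
p_fix = vp.sample_individual(pop, fixed, rng=rng)
p_dyn = vp.sample_individual(pop, rcct, rng=np.random.default_rng(1))

print(f"sampled individual: H_i={p_fix.H_i:+.1f}, A_i={p_fix.A_i:.1f}, "
      f"omega_i={p_fix.omega_i:.2f}, delta_i={p_fix.delta_i:.1f} nmol/L")
for label, t in [("March 1 (trough)", 0.0), ("September 1 (peak)", 184 / 365)]:
    pl = float(vp.status_placebo(p_fix, t, pop))
    fx = float(vp.status_fixed_dose(p_fix, t, pop))
    dyn = float(vp.status_concentration_controlled(p_dyn, t, pop))
    print(f"{label:20s}  placebo {pl:5.1f}   fixed-dose {fx:5.1f}   "
          f"concentration-controlled {dyn:5.1f}  (nmol/L)")

print("\nThe fixed dose adds most in winter (anti-phase uptake), while the")
print("concentration-controlled scheme simply floors the curve at rho_i.")
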