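"""Why thin sections miss membrane intrusions: the inverse Buffon's needle.

A linear structure of length L inside a section of thickness d survives
sectioning intact only if it crosses no section boundary — exactly the
complement of Buffon's needle crossing event.  This script evaluates the
closed-form intact and half-intact probabilities across section thicknesses
and verifies the closed form against a Monte-Carlo experiment.
"""

import numpy as np

from voxtract.sampling_models import (NeedleModel, p_intact, p_half_intact,
                                      p_intact_mc, intact_curve)

L = 367.5  # nm: mean observed intrusion length

print(f"structure length L = {L} nm")
print(f"{'section d (nm)':>15} {'P(intact)':>10} {'P(>=half)':>10}")
for d in (100.0, 367.5, 1000.0, 5000.0):
    m = NeedleModel(L, d)
    print(f"{d:>15.1f} {p_intact(m):>10.3f} {p_half_intact(m):>10.3f}")

print()
print("In a standard 100-nm TEM section, fewer than 9% of such intrusions")
print("appear whole, and only ~18% show even half their length — deep")
print("volumes (d = 5000 nm captures >95%) are required to see them.")

print()
print("Monte-Carlo cross-check at d = 100 nm:")
m = NeedleModel(L, 100.0)
est, se = p_intact_mc(m, n=1_000_000, seed=0)
print(f"  closed form {p_intact(m):.4f}  vs  MC {est:.4f} +/- {se:.4f}")

df = intact_curve(L, np.geomspace(50, 5000, 9))
print()
print("detection-probability curve (9 log-spaced depths):")
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
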