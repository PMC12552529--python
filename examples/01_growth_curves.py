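"""Evaluate the four growth-curve families and their inflection points.

Builds one curve per family at realistic chicken-growth parameters and
prints the expected weight at a few ages plus the inflection geometry.
The inflection weight fraction is what distinguishes the sigmoids:
logistic A/2, Gompertz A/e ~ 0.368 A, von Bertalanffy (2/3)^3 A ~ 0.296 A;
the Brody form has no inflection at all.
"""

import bayesgrowth as bg

curves = {
    "logistic": bg.GrowthCurve("logistic", A=2100.0, B=64.0, K=0.030),
    "gompertz": bg.GrowthCurve("gompertz", A=2100.0, B=64.0, K=0.018),
    "von_bertalanffy": bg.GrowthCurve("von_bertalanffy", A=2109.8, B=64.2,
                                      K=0.0152),
    "brody": bg.GrowthCurve("brody", A=2100.0, B=0.97, K=0.008),
}

ages = [0, 28, 64, 112, 336]
print(f"{'family':<16} " + " ".join(f"t={t:<4}" for t in ages) + "  inflection")
for name, curve in curves.items():
    weights = " ".join(f"{bg.mean_weight(curve, t):6.0f}" for t in ages)
    ip = bg.inflection_point(curve)
    tail = f"t={ip[0]:.1f} d, {ip[1]:.0f} g ({ip[1]/curve.A:.3f} A)" if ip \
        else "none"
    print(f"{name:<16} {weights}  {tail}")

print(
    "\nEach row is the expected weight (g) along one curve; the last column"
    "\nshows where the growth rate peaks and which fraction of the mature"
    "\nweight has been reached there."
)
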