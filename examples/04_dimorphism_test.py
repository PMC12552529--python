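"""Savage-Dickey test of sexual dimorphism in the growth parameters.

Fits the von Bertalanffy model to each sex independently, then computes
the Bayes factor BF01 for H0: theta_male = theta_female for each of A, B
and K.  BF01 is the posterior density of the between-sex difference at
zero divided by its prior density at zero; values above 1 favour equality,
values below 1 favour dimorphism (read on Jeffreys' scale).
"""

import bayesgrowth as bg

data = bg.generate_mean_weights(seed=3)
fit_f = bg.fit_growth_model("von_bertalanffy", data["female"],
                            config=bg.ChainConfig(seed=1))
fit_m = bg.fit_growth_model("von_bertalanffy", data["male"],
                            config=bg.ChainConfig(seed=2))

table = bg.run_dimorphism_suite(fit_m, fit_f, seed=0)
with __import__("pandas").option_context("display.width", 120):
    print(table[["hypothesis", "bf01", "p_h0", "label"]].to_string(index=False))

print(
    "\nThe generating truth differs between sexes only in the asymptote"
    "\n(females ~2110 g, males ~2560 g), so the A row shows decisive"
    "\nevidence against equality while B and K favour H0."
)
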