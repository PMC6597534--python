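#!/usr/bin/env python
"""Recover the allometric constants and recompute the EQ table.

Fits the meningeal correction m(V) = c*V^d and the Manger reference
allometry EQ = M_brain / (a*M_body^b) from the packaged trait table, then
recomputes brain mass and EQ for every specimen and reports the largest
deviations from the printed values.

Writes results/allometry_constants.json and results/eq_table.csv.
"""

import json
from pathlib import Path

import numpy as np

from probrain import allometry, synthetic

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

fx = synthetic.fixtures()
conv = allometry.fit_meningeal_params(fx.table)
eqp = allometry.fit_eq_params(fx.table)
table = allometry.compute_eq_table(fx.table, conv, eqp)

df = table.df
pro = df[df.group == "proboscidean"]
brain_err = (pro["brain_g_recomputed"] - pro["brain_g"]).abs() / pro["brain_g"]
eq_err = (pro["eq_recomputed"] - pro["eq"]).abs()

print(f"meningeal fraction: mean {conv.fraction:.4f}, allometric m(V) = "
      f"{conv.coeff:.4f} * V^{conv.exponent:.4f}")
print(f"EQ reference allometry: a = {eqp.a:.5f}, b = {eqp.b:.4f} "
      f"(log-space residual sd {eqp.residual_sd:.4f})")
print(f"brain-mass reproduction: max relative error "
      f"{brain_err.max():.4%} ({pro.loc[brain_err.idxmax(), 'specimen_id']})")
print(f"EQ reproduction: max |error| {eq_err.max():.4f} "
      f"({pro.loc[eq_err.idxmax(), 'specimen_id']}); all 26 within +/-0.03: "
      f"{bool((eq_err <= 0.03).all())}")

table.to_csv(OUT / "eq_table.csv")
with open(OUT / "allometry_constants.json", "w") as fh:
    json.dump({
        "meningeal_fraction_mean": conv.fraction,
        "meningeal_coeff": conv.coeff,
        "meningeal_exponent": conv.exponent,
        "rho_g_per_cm3": conv.rho,
        "eq_a": eqp.a,
        "eq_b": eqp.b,
        "eq_residual_sd": eqp.residual_sd,
        "max_brain_rel_error": float(brain_err.max()),
        "max_eq_abs_error": float(eq_err.max()),
    }, fh, indent=2)
print(f"wrote {OUT/'eq_table.csv'} and {OUT/'allometry_constants.json'}")
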