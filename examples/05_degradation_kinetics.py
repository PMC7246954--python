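"""Reporter decay fitting and the steady-state X = s/d regression.

Simulates shut-off luminescence tracks for eight C-terminal variants with
a shared synthesis rate, fits per-replicate log-linear decays over the
2-8 h points, and regresses steady-state expression on 1/d to ask how
much of the expression spread degradation alone explains.
"""

import numpy as np

from termbias.kinetics import fit_decay, fold_difference, half_life, normalize_series, steady_state_fit
from termbias.simulate import LuminescenceConfig, gen_luminescence

s = 0.147  # arbitrary-unit synthesis rate shared by all variants
rates = {"NK": 0.105, "K": 0.098, "D": 0.072, "T": 0.17, "P": 0.147,
         "F": 0.185, "L": 0.26, "WL": 0.35}
cfg = LuminescenceConfig(
    variants={v: (s / d, d) for v, d in rates.items()},  # X0 = s/d at steady state
    cv=0.05,
    replicates=3,
    seed=9,
)
ts, truth = gen_luminescence(cfg)

norm, steady = normalize_series(ts, reference="P")
fits, summary = fit_decay(norm)
print(summary.assign(half_life=summary["half_life"].round(2)).to_string(index=False))

x = steady.groupby("variant")["steady_state"].mean()
d = summary.set_index("variant")["d_mean"]
res = steady_state_fit(x[d.index].to_numpy(), d.to_numpy())
print(f"\nsteady-state X vs 1/d: adjusted R^2 = {res['adj_r2']:.2f}")

dmax, dmin = summary["d_mean"].max(), summary["d_mean"].min()
print(f"degradation-rate range: {fold_difference(dmax, dmin):.1f}-fold "
      f"(half-lives {half_life(dmax):.1f} to {half_life(dmin):.1f} h)")
print(
    "\nBecause the simulated variants share one synthesis rate, essentially "
    "all of the steady-state expression spread is explained by degradation; "
    "noise in the tracks keeps the adjusted R^2 just below 1."
)
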