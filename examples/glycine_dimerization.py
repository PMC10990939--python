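"""TMP-driven glycine dimerization: kinetics fit and batch behaviour.

The dimerization scheme (activation of glycine by trimetaphosphate,
dimerization, and three hydrolysis channels) is integrated at the
standard experimental design — a TMP titration read out after 16 h plus a
120 h time series — and the rate constants are then re-fitted from that
synthetic data to demonstrate the identifiability of the scheme.
"""

import numpy as np
import pandas as pd

from thermotrap import REFERENCE_RATES, fit_k4, fit_rates, integrate_batch, reaction_yield
from thermotrap.synthetic import synth_reaction_data

# --- separate TMP-only hydrolysis experiment fixes k4 ---------------------
times = np.linspace(0.0, 120 * 3600.0, 13)
decay = 2e-4 * np.exp(-REFERENCE_RATES.k4 * times)
k4 = fit_k4(times, decay)["k4"]
print(f"k4 from TMP-decay fit: {k4:.3e} 1/s (half-life {np.log(2)/k4/86400:.1f} days)")

# --- simultaneous fit of the remaining rates ------------------------------
titration, series = synth_reaction_data(REFERENCE_RATES, noise_sigma=0.0, n_replicates=1)
fitted = fit_rates(pd.concat([titration, series]), k4=k4, seed=0)
print("recovered rate constants (generating value in parentheses):")
for name in ("k1", "k2", "k3", "k5"):
    print(f"  {name} = {getattr(fitted, name):.3e}  ({getattr(REFERENCE_RATES, name):.1e})")

# --- batch outcomes across concentrations ---------------------------------
for g0, t0 in [(1e-6, 1e-6), (1e-3, 1e-3), (0.1, 0.1)]:
    out = integrate_batch({"Gly": g0, "TMP": t0}, fitted, duration=120 * 3600)
    y = reaction_yield(out["GlyGly"].iloc[-1], out["Gly"].iloc[-1])
    print(
        f"[Gly]0 = [TMP]0 = {g0:.0e} M: GlyGly after 120 h = "
        f"{out['GlyGly'].iloc[-1]:.2e} M, yield {y:.2e}"
    )
print(
    "At micromolar feeds the product is femtomolar; enriching both"
    " reactants by the heat-flow network raises the yield by orders of"
    " magnitude."
)
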