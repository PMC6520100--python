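"""Select the distance-gradient model family by AIC.

Five families of H-ratio-versus-distance models are fitted to an annulus
profile: linear, quadratic, cubic, exponential (b*exp(c*d)) and exponential
with intercept (a + b*exp(c*d)).  The reported best family is the most
parsimonious one within 2 AIC of the minimum: models within ~2 AIC are
conventionally regarded as equivalently supported, so extra parameters must
buy a real improvement.

Run:  python examples/03_gradient_model_selection.py
"""

import numpy as np

import boldfractal as bf

rng = np.random.default_rng(42)
distance = np.linspace(1.0, 29.0, 15)  # 2-mm band centres out to 30 mm

# a suppression-then-overshoot quadratic with realistic measurement noise
truth = 0.91 + 0.0105 * distance - 0.00026 * distance**2
ratio = truth + rng.normal(0.0, 0.004, size=distance.size)

fits = bf.fit_gradient_models(distance, ratio, seed=0)
print(bf.fits_table(fits).round(4).to_string(index=False))

best = bf.select_best(fits)
print()
print(f"best family: {best.family}")
print(f"coefficients: {np.round(best.coefficients, 5)}")
print(f"R^2 = {best.r_squared:.4f}, AIC = {best.aic:.1f}")

# the same data under strict minimum-AIC selection, for comparison
strict = bf.select_best(fits, parsimony_margin=0.0)
print(f"strict minimum-AIC choice: {strict.family}")
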