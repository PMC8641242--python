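"""Arousal quantities as quadratics in the prediction error.

For one sample (n = 1), prior variance 3 and sensory variance 0.5 — the
reference setting of the variance sweeps — print the (A, B) coefficients
of gain, uncertainty and free energy, and evaluate them at a prediction
error of 2.
"""

from collative import (
    free_energy_quadratic,
    information_gain_quadratic,
    uncertainty_quadratic,
)

n, s_p, s_l = 1, 3.0, 0.5
S = s_l  # sample variance matched to the sensory variance

gain = information_gain_quadratic(n, s_p, s_l)
uncertainty = uncertainty_quadratic(n, s_p, s_l, S)
free_energy = free_energy_quadratic(n, s_p, s_l, S)

print(f"{'quantity':<12} {'A (gradient)':>14} {'B (intercept)':>14} {'value at δ=2':>14}")
for form in (gain, uncertainty, free_energy):
    print(
        f"{form.quantity:<12} {form.gradient_coeff:>14.6f} "
        f"{form.intercept:>14.6f} {form(2.0):>14.6f}"
    )
print()
print("A_F = A_G + A_U and B_F = B_G + B_U exactly: free energy is the sum")
print("of novelty content (gain) and uncertainty at every prediction error.")
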