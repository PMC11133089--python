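"""A small Monte Carlo comparison of the t-test and model-based tests.

Runs 100 replications of two dichotomous-item conditions at n_k = 500 --
full invariance versus three inflated focal unique variances -- and
tabulates rejection rates of the scale-score t-test alongside the
factor-mean Wald test in the correctly specified strict model.  With a
zero factor-mean difference both rates estimate type I error; the t-test
inflates under noninvariance while the strict model does not.

Increase ``R`` for stable rates; 100 keeps the script under a minute.
"""

from ordmi import acceptable_range, make_condition, run_grid

R = 100
grid = [
    make_condition("negatively_skewed", 500, 2, 0, 1.0, 0.0),       # invariant
    make_condition("negatively_skewed", 500, 2, 3, 1.5**2, 0.0),    # 3 noninvariant
]

table = run_grid(grid, n_reps=R, seed=7, analyses=("ttest", "strict_wald"))
cols = ["condition", "analysis", "rejection_rate", "raw_bias", "convergence_rate"]
print(table[cols].round(3).to_string(index=False))

lo, hi = acceptable_range(0.05, R)
print(f"\nAcceptable type-I-error band at R={R}: [{lo:.2f}%, {hi:.2f}%]")
print("Under noninvariance the t-test rate leaves the band; the strict-model "
      "Wald test stays near the nominal 5%.")
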