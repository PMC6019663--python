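"""Exact binomial confidence intervals for small feasibility counts.

When novice operators attempt a view only a handful of times, proportions
like 2/10 need exact (Clopper-Pearson) intervals rather than normal
approximations.  The interval comes from Beta-distribution quantiles and
has guaranteed >= 95% coverage at any n.
"""

from diamotion import clopper_pearson

counts = [
    ("left mid-clavicular view obtained", 2, 10),
    ("left mid-clavicular view failed", 8, 10),
    ("right mid-clavicular view obtained", 9, 10),
    ("mid-axillary view obtained (either side)", 10, 10),
]

for label, k, n in counts:
    ci = clopper_pearson(k, n)
    print(f"{label:42s} {k:2d}/{n}  ->  {100 * ci.point:3.0f}% "
          f"(95% CI {ci.ci_low:.2f}-{ci.ci_high:.2f})")

print()
print("At k = n the lower bound is (0.025)^(1/n); the interval never")
print("collapses to a point even when every attempt succeeds.")
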