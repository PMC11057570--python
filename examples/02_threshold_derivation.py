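"""Reproduce the structural derivation of the fixed diagnostic cutoff.

The cutoff does not come from any cohort: it is the midpoint of the
minimum score that already carries a count-based diagnosis (three axes
exactly at threshold, two at zero) and the supremum score that does not
(two axes at the maximum, three just below threshold).
"""

from rmrs import derive_diagnostic_threshold, rmrs_value

d = derive_diagnostic_threshold()
print(f"min RMRS with three risk factors: {d.min_three:.3f}")
print(f"sup RMRS with two risk factors:   {d.max_two:.3f}")
print(f"fixed diagnostic threshold:       {d.threshold:.3f}")

# The theoretical per-count range endpoints come from the same kind of
# boundary configurations:
eps = 1e-9
print("\ntheoretical RMRS range per risk-factor count:")
for k, (lo_cfg, hi_cfg) in {
    2: ([0.5, 0.5, 0, 0, 0], [1, 1, 0.5 - eps, 0.5 - eps, 0.5 - eps]),
    3: ([0.5, 0.5, 0.5, 0, 0], [1, 1, 1, 0.5 - eps, 0.5 - eps]),
    4: ([0.5, 0.5, 0.5, 0.5, 0], [1, 1, 1, 1, 0.5 - eps]),
    5: ([0.5] * 5, [1.0] * 5),
}.items():
    print(f"  k={k}: {rmrs_value(lo_cfg):.3f} - {rmrs_value(hi_cfg):.3f}")
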