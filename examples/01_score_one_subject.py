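"""Score a single subject and inspect the pieces of the calculation."""

from rmrs import SubjectRecord, score_subject

# A Korean male with mildly elevated glucose and triglycerides, waist at
# the cutoff, and everything else in the normal range.
subject = SubjectRecord(
    glucose=108, sbp=122, dbp=78, triglycerides=170, hdl=47, waist=90,
    sex="male", region="korean", id="example",
)

result = score_subject(subject)

print("scaled axes (0.5 = at threshold):")
for name, value in zip(("GL", "BP", "TG", "HDL", "WC"), result.scaled.as_tuple()):
    print(f"  {name:>3}: {value:.3f}")
print(f"risk-factor count:  {result.risk_factor_count}")
print(f"RMRS:               {result.rmrs:.3f}")
print(f"MetS by count:      {result.diagnosis_by_count}")
print(f"MetS by RMRS>=0.547: {result.diagnosis_by_rmrs}")

# The scaled axes read directly: GL and TG sit above 0.5 (above their
# diagnostic cutoffs), WC exactly at it. The RMRS aggregates all 10
# three-factor triads, so near-threshold factors contribute risk that the
# dichotomous count ignores.
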