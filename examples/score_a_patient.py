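"""Score a single patient with qSOFA, SIRS and qSIRS.

Builds one observation with admission vitals, dichotomizes each criterion,
and prints the three point totals with their positivity flags (every score
is positive at >= 2 points).
"""

from qsirs import PatientObservation, compute_scores, evaluate_criteria

patient = PatientObservation(
    patient_id="example-1",
    age=58,
    sex="female",
    sbp=96.0,    # mmHg; <= 100 counts for qSOFA and qSIRS
    temp=38.9,   # degC; > 38.3 counts for SIRS and qSIRS
    hr=104.0,    # beats/min; > 90 counts for SIRS and qSIRS
    rr=21.0,     # breaths/min; > 20 counts for SIRS, >= 20 for qSIRS, but not qSOFA (< 22)
    gcs=15,
    wbc=9500.0,  # cells/mm3; within 4,000-12,000, normal
)

panel = evaluate_criteria(patient)
scores = compute_scores(panel)

print("criterion flags:", panel)
print(f"qSOFA: {scores.qsofa_points} point(s), positive={scores.qsofa_positive}")
print(f"SIRS:  {scores.sirs_points} point(s), positive={scores.sirs_positive}")
print(f"qSIRS: {scores.qsirs_points} point(s), positive={scores.qsirs_positive}")
print(
    "\nA positive score flags elevated 30-day mortality risk; note how the\n"
    "combined qSIRS pools items from both component scores (respiratory\n"
    "rate counted once), so it can be positive when each component alone\n"
    "is not."
)
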