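"""Triage two patients with the shipped reference models.

First a 65-year-old man without comorbidity, PSA 4.0 ng/mL, free PSA
12% — a suspicious free-PSA ratio at a long life expectancy.  Then the
same blood values in a 75-year-old with Charlson 2+: his competing
mortality erases the benefit, so he is not referred.
"""

from pcatriage import PatientProfile, triage_patient

profile = PatientProfile(age=65, psa=4.0, free_psa_pct=0.12, charlson="0")
report = triage_patient(profile)
print(report["text"])
print("Per-criterion classification:", report["advice"]["per_criterion"])

print()

elderly = PatientProfile(age=75, psa=4.0, free_psa_pct=0.12, charlson="2+")
report2 = triage_patient(elderly)
print(report2["text"])
print("Per-criterion classification:", report2["advice"]["per_criterion"])

print()
print("The risk percentage is the probability that a biopsy today would find")
print("ISUP grade >= 2 cancer; the life expectancies are Weibull means; the")
print("gain is the difference in mean survival after applying the trial")
print("hazard ratio (0.84) to the untreated-csPCa curve.")
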