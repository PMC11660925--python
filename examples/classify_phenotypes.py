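"""Classify one patient's phenotype day by day.

A patient diagnosed with RRMS is later given an SPMS diagnosis (day 0 below).
From that day on, every follow-up day is rSPMS if any relapse fell in the
preceding 2 years (half-open 730-day window), else nrSPMS.  One relapse 100
days before the SPMS diagnosis and one at day 6547 produce the classic
rSPMS -> nrSPMS -> rSPMS course.
"""

from msphase import PatientRecord, classify_timeline, transition_pattern

patient = PatientRecord(
    patient_id="example",
    sex="female",
    onset_day=-1500,  # MS onset, ~4 years before the SPMS diagnosis
    rrms_dx_day=-1200,
    spms_dx_day=0,
    end_day=6721,
    end_reason="admin_censor",
    age_at_onset=30.0,
)
relapses = [-100, 6547]

timeline = classify_timeline(patient, relapses)
print("state intervals (state, first day, last day):")
for interval in timeline.intervals:
    print("  ", interval)
print("SPMS-phase transition pattern:", transition_pattern(timeline))

# The pre-diagnosis relapse keeps the patient rSPMS for 730 - 100 = 630 days,
# so day 630 is the first nrSPMS day; the day-6547 relapse re-enters rSPMS
# until the end of follow-up at day 6721.
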