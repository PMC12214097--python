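"""Apply the clinical outcome rules to a small constructed cohort.

Four responders illustrate every branch of the recurrence rule: a repeat
injection at day 120 (recurrence), documented follow-up past day 365
(no recurrence), loss to follow-up at day 200 (censored), and a repeat
injection at day 380 (no recurrence — outside the 365-day window).
"""
import datetime as dt

from subacrodyn import PatientRecord, VasTriple, classify_early_success, label_recurrence

INJ = dt.date(2021, 1, 1)

success = classify_early_success(VasTriple(6.2, 6.3, 6.5), VasTriple(2.8, 2.8, 2.8))
print(f"VAS 6.2/6.3/6.5 -> 2.8/2.8/2.8: early success = {success} "
      "(rest subdomain improved ~55%, well over the strict 30% bar)")

scenarios = [
    ("repeat injection day 120", dict(repeat_injection_date=INJ + dt.timedelta(days=120))),
    ("documented visit day 400", dict(last_visit_date=INJ + dt.timedelta(days=400))),
    ("lost to phone follow-up, last seen day 200",
     dict(last_visit_date=INJ + dt.timedelta(days=200), phone_contact="no_response")),
    ("repeat injection day 380", dict(repeat_injection_date=INJ + dt.timedelta(days=380))),
]
for name, fields in scenarios:
    rec = PatientRecord(id=name, age=60, injection_date=INJ, **fields)
    label = label_recurrence(rec, early_success=True)
    print(f"{name:45s} -> {label.recurrence_status:13s} at day {label.time_days}")
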