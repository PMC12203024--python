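"""Turn raw dispense records into anonymized daily-dose strings.

A patient takes quetiapine twice a day, 1 x 200 mg + 2 x 25 mg per dispense.
The pipeline sums pill counts within (patient, date, drug, strength), renders
"{quantity} pill(s) of {strength}" terms largest strength first, and drops
the patient identifier and date — the resulting string is the anonymized
classifier input and cannot be linked back to a person.
"""

from datetime import date
from fractions import Fraction

from doseatc import DrugRecord, build_dose_strings

records = []
for dispense_time in ("08:00", "19:00"):
    records.append(DrugRecord("patient-7", date(2024, 3, 1), "PMS-Quetiapine", "200 mg", Fraction(1)))
    records.append(DrugRecord("patient-7", date(2024, 3, 1), "PMS-Quetiapine", "25 mg", Fraction(2)))
# a second patient on an identical regimen collapses into the same string
for dispense_time in ("08:00", "19:00"):
    records.append(DrugRecord("patient-9", date(2024, 3, 4), "pms-quetiapine", "200 mg", Fraction(1)))
    records.append(DrugRecord("patient-9", date(2024, 3, 4), "pms-quetiapine", "25 mg", Fraction(2)))

for text in build_dose_strings(records):
    print(text)
# -> one distinct string: daily totals of 2 x 200 mg and 4 x 25 mg,
#    no patient id, no date.
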