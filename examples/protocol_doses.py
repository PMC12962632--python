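"""Cumulative protocol chemotherapy doses and cross-trial fold ratios.

Loads the three packaged trial regimens, prints the drug x regimen
cumulative-dose table (mg/m2 of body surface area) and the fold
differences between trials.  The large spread — e.g. one trial
prescribing ~6x the vincristine of another for equivalent survival —
is what motivates dose de-escalation toward a common backbone.
"""

from mbrisk import cumulative_dose, dose_ratio, dose_table, load_regimens

regimens = load_regimens()

print("Cumulative prescribed doses (mg/m2):")
print(dose_table(list(regimens.values())).to_string(float_format="%.0f"))

print("\nFold differences between trials:")
print(f"  cisplatin   ACNS0331 / SJMB03   = {dose_ratio(regimens['ACNS0331'], regimens['SJMB03'], 'cisplatin'):.2f}")
print(f"  cyclophos.  ACNS0332 / ACNS0331 = {dose_ratio(regimens['ACNS0332'], regimens['ACNS0331'], 'cyclophosphamide'):.2f}")
print(f"  vincristine ACNS0331 / SJMB03   = {dose_ratio(regimens['ACNS0331'], regimens['SJMB03'], 'vincristine'):.2f}")
print(f"  vincristine ACNS0332 / SJMB03   = {dose_ratio(regimens['ACNS0332'], regimens['SJMB03'], 'vincristine'):.2f}")
print(f"\nSJMB03 cisplatin cap: {cumulative_dose(regimens['SJMB03'], 'cisplatin'):.0f} mg/m2 "
      "(the level above which no survival benefit was seen)")
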