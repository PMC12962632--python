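# Protocol chemotherapy regimens transcribed from the three trials'
# treatment plans.  Doses are per body surface area (mg/m2); counts are
# administrations per cycle; `cycles` multiplies a whole phase.
# Absolute mg caps (e.g. vincristine max 2.0 mg) are intentionally not
# modelled.  Phases tagged with `arm` belong to a randomized add-on and
# can be included or dropped at load time.
regimens:
  ACNS0331:
    metadata:
      csi_dose_gy: [18.0, 23.4]        # LDCSI randomization vs SDCSI
      boost_ctv_cm: 1.5                # IFRT arm; PFRT arm boosts the whole posterior fossa
      boost_dose_gy: 54.0
    phases:
      - label: chemoradiotherapy
        cycles: 1
        administrations:
          - {drug: vincristine, dose_mg_m2: 1.5, count: 6}   # once weekly, weeks 2-7
      - label: maintenance cycle A
        cycles: 6                                            # AABAABAAB pattern
        administrations:
          - {drug: lomustine, dose_mg_m2: 75.0, count: 1}
          - {drug: vincristine, dose_mg_m2: 1.5, count: 3}   # days 1, 8, 15
          - {drug: cisplatin, dose_mg_m2: 75.0, count: 1}
      - label: maintenance cycle B
        cycles: 3
        administrations:
          - {drug: cyclophosphamide, dose_mg_m2: 1000.0, count: 2}  # days 1-2
          - {drug: vincristine, dose_mg_m2: 1.5, count: 2}          # days 1, 8
  SJMB03:
    metadata:
      csi_dose_gy: [23.4, 39.6]        # average-risk SDCSI; high-risk HDCSI 36-39.6
      boost_ctv_cm: 1.0
      boost_dose_gy: 55.8
    phases:
      - label: high-dose chemotherapy with stem-cell rescue
        cycles: 4
        administrations:
          - {drug: vincristine, dose_mg_m2: 1.0, count: 2}          # days -4 and +6
          - {drug: cisplatin, dose_mg_m2: 75.0, count: 1}           # day -4
          - {drug: cyclophosphamide, dose_mg_m2: 2000.0, count: 2}  # days -3 and -2
  ACNS0332:
    metadata:
      csi_dose_gy: [36.0, 39.6]
      boost_ctv_cm: null               # whole posterior fossa boost
      boost_dose_gy: 55.8
    phases:
      - label: chemoradiotherapy
        cycles: 1
        administrations:
          - {drug: vincristine, dose_mg_m2: 1.5, count: 6}   # once weekly, weeks 1-6
      - label: chemoradiotherapy carboplatin arm
        cycles: 1
        arm: carboplatin
        administrations:
          - {drug: carboplatin, dose_mg_m2: 35.0, count: 30}  # daily during radiotherapy
      - label: maintenance
        cycles: 6
        administrations:
          - {drug: cisplatin, dose_mg_m2: 75.0, count: 1}           # day 1
          - {drug: vincristine, dose_mg_m2: 1.5, count: 2}          # days 1, 8
          - {drug: cyclophosphamide, dose_mg_m2: 1000.0, count: 2}  # days 1-2
      - label: isotretinoin arm
        cycles: 12
        arm: isotretinoin
        administrations:
          - {drug: isotretinoin, dose_mg_m2: 80.0, count: 14}  # 14 dosing days per cycle
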