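# Published national surveillance counts, Brazil 2015-2022: obstetric
# hospitalizations in the public (SIH/SUS) and private (ANS) administrative
# databases, severe-maternal-morbidity (PLTC) case counts per criterion,
# and (death, alive) cells per criterion among known-outcome episodes.
#
# These counts are inputs to the odds-ratio-of-death validity reconstruction:
# each criterion's 2x2 table is (deaths_with, alive_with) against the
# complement of the known-outcome totals. "printed_or" is the odds ratio as
# published (null where a zero cell made it undefined). The private-schema
# death_table header totals as published are internally inconsistent with the
# deaths-by-count table; reconstruction there is reliable only for rows
# consistent with the deaths-by-count totals (see docs/methods.md).
public:
  n_obstetric: 18807757
  deaths_total: 7456
  alive_total: 18621293
  smm_cases: 1600796
  criterion_cases:
    abruptio_placentae: 61056
    ectopic_pregnancy: 130436
    postpartum_haemorrhage: 22546
    ruptured_uterus: 4287
    severe_preeclampsia: 198247
    eclampsia: 56430
    severe_hypertension: 652396
    hypertensive_encephalopathy: 20
    endometritis: 51966
    pulmonary_oedema: 208
    respiratory_failure: 10485
    seizures: 627
    sepsis: 4218
    shock: 1385
    thyroid_crisis: 12
    blood_transfusion: 186101
    central_venous_access: 2967
    hysterectomy: 12523
    icu_admission: 100585
    prolonged_stay: 292625
    non_anaesthetic_intubation: 2734
    surgical_intervention: 131494
  group_cases:
    HAEMORRHAGIC: 218017
    HYPERTENSIVE: 865446
    OTHER_SYSTEMIC: 68514
    MANAGEMENT: 636559
  death_table:  # criterion: [deaths_with, alive_with, printed_or]
    abruptio_placentae: [160, 59899, 6.80]
    ectopic_pregnancy: [85, 128931, 1.65]
    postpartum_haemorrhage: [240, 21096, 29.32]
    ruptured_uterus: [34, 4104, 20.78]
    severe_preeclampsia: [320, 190572, 4.34]
    eclampsia: [330, 52443, 16.40]
    severe_hypertension: [544, 636331, 2.22]
    hypertensive_encephalopathy: [2, 14, 356.88]
    endometritis: [162, 50169, 8.22]
    pulmonary_oedema: [28, 160, 438.70]
    respiratory_failure: [217, 10110, 55.18]
    seizures: [9, 586, 38.40]
    sepsis: [219, 3819, 147.52]
    shock: [269, 1006, 692.78]
    thyroid_crisis: [0, 12, null]
    blood_transfusion: [2181, 175881, 43.36]
    central_venous_access: [395, 2014, 517.17]
    hysterectomy: [513, 10660, 129.00]
    icu_admission: [2579, 89783, 109.15]
    prolonged_stay: [568, 288306, 5.24]
    non_anaesthetic_intubation: [11, 2654, 10.37]
    surgical_intervention: [453, 127123, 9.41]
  group_death_table:
    HAEMORRHAGIC: [504, 213774, 6.24]
    HYPERTENSIVE: [1070, 839754, 3.55]
    OTHER_SYSTEMIC: [785, 65630, 33.27]
    MANAGEMENT: [3556, 614525, 26.72]
  smm_death_table: [4104, 1554823, 13.44]
  deaths_by_count:  # [n_criteria, deaths, alive]
    - [0, 3352, 17066470]
    - [1, 1436, 1315954]
    - [2, 1186, 189619]
    - [3, 806, 39131]
    - [4, 419, 8028]
    - [5, 166, 1668]
    - [6, 68, 341]
    - [7, 11, 68]
    - [8, 7, 12]
    - [9, 4, 2]
    - [10, 1, 0]
private:
  n_obstetric: 3776986
  deaths_total: 4276
  alive_total: 3576689
  smm_cases: 275731
  criterion_cases:
    abruptio_placentae: 2839
    ectopic_pregnancy: 30112
    postpartum_haemorrhage: 1302
    ruptured_uterus: 122
    severe_preeclampsia: 8183
    eclampsia: 2233
    severe_hypertension: 50899
    hypertensive_encephalopathy: 3
    endometritis: 2093
    pulmonary_oedema: 23
    respiratory_failure: 35681
    seizures: 107
    sepsis: 698
    shock: 379
    thyroid_crisis: 4
    blood_transfusion: 12806
    central_venous_access: 4482
    hysterectomy: 10670
    icu_admission: 95596
    prolonged_stay: 56980
    non_anaesthetic_intubation: 308
    surgical_intervention: 17911
  group_cases:
    HAEMORRHAGIC: 34374
    HYPERTENSIVE: 61181
    OTHER_SYSTEMIC: 38836
    MANAGEMENT: 172780
  death_table:
    abruptio_placentae: [15, 2634, 4.78]
    ectopic_pregnancy: [8, 28847, 0.23]
    postpartum_haemorrhage: [2, 1243, 1.35]
    ruptured_uterus: [2, 111, 15.08]
    severe_preeclampsia: [6, 7408, 0.68]
    eclampsia: [12, 1967, 5.11]
    severe_hypertension: [59, 47539, 1.04]
    hypertensive_encephalopathy: [0, 3, null]
    endometritis: [8, 1949, 3.44]
    pulmonary_oedema: [0, 17, null]
    respiratory_failure: [282, 30955, 8.09]
    seizures: [2, 92, 18.19]
    sepsis: [8, 602, 11.13]
    shock: [20, 320, 52.52]
    thyroid_crisis: [0, 4, 0.00]
    blood_transfusion: [206, 11287, 15.99]
    central_venous_access: [183, 3488, 45.80]
    hysterectomy: [56, 10037, 4.72]
    icu_admission: [769, 84250, 9.09]
    prolonged_stay: [234, 46139, 4.43]
    non_anaesthetic_intubation: [1, 291, 2.87]
    surgical_intervention: [68, 16772, 3.43]
  group_death_table:
    HAEMORRHAGIC: [27, 32834, 0.69]
    HYPERTENSIVE: [77, 56792, 1.14]
    OTHER_SYSTEMIC: [313, 33818, 8.27]
    MANAGEMENT: [914, 150975, 6.17]
  smm_death_table: [1016, 246858, 4.15]
  deaths_by_count:
    - [0, 3320, 3363023]
    - [1, 487, 183732]
    - [2, 267, 24870]
    - [3, 136, 4089]
    - [4, 52, 814]
    - [5, 14, 146]
    - [6, 0, 14]
    - [7, 0, 1]
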