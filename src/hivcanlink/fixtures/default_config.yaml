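age_max: 90.0
age_median: 40.0
age_min: 15.0
age_sigma: 0.28
cancer_after_hiv_prob: 0.9
cancer_fraction: 0.3
cancer_type_weights:
  BCC: 0.04
  Bladder: 0.01
  Bone: 0.01
  Breast: 0.09
  Burkitt lymphoma: 0.02
  Cervix: 0.26
  Hodgkin lymphoma: 0.02
  Kaposi Sarcoma: 0.16
  Kidney: 0.01
  Melanoma: 0.01
  Mesothelioma: 0.005
  Non Hodgkin lymphoma: 0.08
  Other: 0.18
  Pancreas: 0.005
  Prostate: 0.03
  Skin other: 0.03
  Stomach: 0.015
  Testis: 0.005
  Thyroid: 0.01
  Tongue: 0.01
corruption:
  dob_error_rate: 0.03
  identifier_missing_rate: 0.15
  nickname_swap_rate: 0.02
  typo_ops:
    deletion: 0.15
    insertion: 0.15
    substitution: 0.4
    transposition: 0.3
  typo_rate: 0.05
female_fraction: 0.709
hiv_away_province_rate: 0.1
hiv_records_per_person: 2.5
hiv_result_label_weights:
  negative: 0.2
  positive: 0.7
  unknown: 0.1
missing_diagnosis_province_rate: 0.02
mobility:
  EC:
    EC: 0.8079215535473947
    FS: 0.003653143626225726
    GAU: 0.049990386464141515
    KZN: 0.009805806575658528
    LIM: 0.0005768121515093252
    MPU: 0.0032686021918861756
    NC: 0.003460872909055951
    NW: 0.004422226494904826
    WC: 0.11690059603922323
  FS:
    EC: 0.003286294219988401
    FS: 0.8215735549971003
    GAU: 0.11192731490431085
    KZN: 0.003092982795283201
    LIM: 0.003286294219988401
    MPU: 0.007539145563502803
    NC: 0.007152522714092403
    NW: 0.010052194084670405
    WC: 0.03208969650106321
  GAU:
    EC: 0.004531350046791114
    FS: 0.019307491503718664
    GAU: 0.8709057774713097
    KZN: 0.019258237698862236
    LIM: 0.015859725163768903
    MPU: 0.0465940993941782
    NC: 0.002117913608826282
    NW: 0.011131359897552085
    WC: 0.010294045214992859
  KZN:
    EC: 0.010723248916267396
    FS: 0.011521788729180926
    GAU: 0.4681724845995893
    KZN: 0.43417750399269905
    LIM: 0.00296600501939311
    MPU: 0.06114533424595026
    NC: 0.0007985398129135296
    NW: 0.0031941592516541184
    WC: 0.00730093543235227
  LIM:
    EC: 0.0016200891049007696
    FS: 0.009113001215066828
    GAU: 0.17274200081004457
    KZN: 0.0028351559335763467
    LIM: 0.7808829485621709
    MPU: 0.025313892264074524
    NC: 0.0002025111381125962
    NW: 0.0044552450384771165
    WC: 0.0028351559335763467
  MPU:
    EC: 0.0018652076597861229
    FS: 0.013678189505098234
    GAU: 0.3531459835861726
    KZN: 0.0227555334493907
    LIM: 0.021636408853519026
    MPU: 0.5762248196965929
    NC: 0.000994777418552599
    NW: 0.00435215120616762
    WC: 0.005346928624720219
  NC:
    EC: 0.015479876160990712
    FS: 0.03281733746130031
    GAU: 0.05263157894736842
    KZN: 0.0006191950464396285
    LIM: 0.0018575851393188853
    MPU: 0.004953560371517028
    NC: 0.7746130030959752
    NW: 0.011764705882352941
    WC: 0.10526315789473684
  NW:
    EC: 0.005470459518599562
    FS: 0.027789934354485776
    GAU: 0.2474835886214442
    KZN: 0.0024070021881838076
    LIM: 0.01312910284463895
    MPU: 0.006783369803063457
    NC: 0.011159737417943107
    NW: 0.6645514223194748
    WC: 0.021225382932166303
  WC:
    EC: 0.01928079571537873
    FS: 0.0016832440703902067
    GAU: 0.01928079571537873
    KZN: 0.0026013771996939556
    LIM: 0.000612088752869166
    MPU: 0.001224177505738332
    NC: 0.005355776587605203
    NW: 0.001224177505738332
    WC: 0.9487375669472073
n_entities: 5000
province_weights:
  EC: 0.12
  FS: 0.05
  GAU: 0.26
  KZN: 0.19
  LIM: 0.1
  MPU: 0.08
  NC: 0.02
  NW: 0.07
  WC: 0.11
race_weights:
  Asian: 0.005986996990910366
  Black: 0.896412479146853
  Coloured: 0.05014109979887432
  White: 0.047459424063362385
seed: 20040101
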