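# Default phrase banks for the synthetic structured-report simulator.
#
# {m} is substituted with a generated measurement string (e.g. "1.2 x 0.8 cm"),
# {date} with an in-text date string.  The "stable_positive" bank deliberately
# overlaps the "negative_stable" bank verbatim: a follow-up of a known
# metastasis and an uneventful follow-up can read identically, so the target
# report alone cannot distinguish them — only the patient's history can.
negative_common:
  - "No suspicious findings."
  - "Unremarkable."
  - "No evidence of metastatic disease."
  - "No focal lesion identified."
  - "Normal appearance."
negative_stable:
  - "No significant interval change."
  - "Stable exam with no significant change."
  - "Stable."
stable_positive:
  - "No significant interval change."
  - "Stable exam with no significant change."
  - "Stable."
remeasured_positive:
  - "Index lesion now measures {m}."
  - "Reference lesion again measures {m}, slightly increased."
  - "Dominant lesion measures {m}, previously noted."
new_positive:
  lungs:
    - "New {m} nodule in the right lower lobe, suspicious for metastasis."
    - "New pulmonary nodule measuring {m}, concerning for metastatic disease."
    - "Interval development of a {m} nodule in the left upper lobe, suspicious for metastasis."
  liver:
    - "New {m} hypodense lesion in the hepatic dome, concerning for metastasis."
    - "Interval development of a {m} hepatic lesion, suspicious for metastatic disease."
  adrenal_glands:
    - "New {m} right adrenal nodule, suspicious for metastatic disease."
    - "Interval enlargement of the left adrenal gland with a {m} nodule, concerning for metastasis."
  default:
    - "New {m} lesion, suspicious for metastasis."
    - "Interval development of a {m} mass, concerning for metastatic disease."
benign:
  lungs:
    - "Calcified granuloma measuring {m}, unchanged, likely benign."
    - "Stable {m} benign-appearing nodule, favored to represent a granuloma."
    - "Tiny {m} nodule, too small to characterize, likely benign."
date_mention:
  - "Comparison with prior exam of {date}."
  - "Compared to study dated {date}."
impression_positive:
  - "Findings compatible with metastatic disease involving the {organs}."
  - "Metastatic disease involving the {organs}, as above."
impression_negative:
  - "No evidence of metastatic disease."
  - "No acute findings."
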