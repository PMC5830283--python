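# Reference calibration of the 9-item liver-stagnation / spleen-deficiency
# severity scale for diarrhoea-predominant IBS, under the two-factor graded
# response model with simple structure: items 1-5 load on the liver-stagnation
# factor, items 6-9 on the spleen-deficiency factor.
#
# a: discrimination vector (one slope per latent dimension, zeros fixed by
#    the loading pattern); d: boundary "easiness" intercepts, one per category
#    boundary, strictly descending.
#
# Transcription note: the published parameter table leaves item 9's first
# discrimination entry blank; it is fixed to 0 here, which is what the
# simple-structure loading pattern dictates for an item of the second factor.
# The metric of the published slopes (probit vs logistic) is not stated in the
# source table; the link below is a default, not a fact about the calibration.
n_dimensions: 2
link: probit
dimension_labels: [liver_stagnation, spleen_deficiency]
category_labels: [none, mild, middle, serious]
items:
  - id: item1
    label: "Irritability and susceptibility to rage"
    a: [2.03, 0.0]
    d: [-0.15, -2.60, -5.39]
  - id: item2
    label: "Depression"
    a: [2.19, 0.0]
    d: [-0.83, -3.10, -5.91]
  - id: item3
    label: "Discomfort aggravated by mental disorders"
    a: [1.29, 0.0]
    d: [-0.39, -3.71, -4.65]
  - id: item4
    label: "Sensation of contracture of the lower abdomen"
    a: [0.84, 0.0]
    d: [-2.51, -4.78, -6.19]
  - id: item5
    label: "Sigh"
    a: [1.12, 0.0]
    d: [-1.10, -3.29, -5.78]
    category_labels: [none, occasionally, sometimes, always]
  - id: item6
    label: "Gastrointestinal rumbling"
    a: [0.0, 2.21]
    d: [-1.95, -5.66, -7.11]
    category_labels: [none, occasionally, sometimes, always]
  - id: item7
    label: "Intestinal flatus from anus"
    a: [0.0, 1.48]
    d: [-0.95, -3.67, -5.59]
  - id: item8
    label: "Anorexia"
    a: [0.0, 0.94]
    d: [-2.51, -5.19, -6.30]
  - id: item9
    label: "Discomforts alleviated after defecation"
    a: [0.0, 0.98]
    d: [-0.49, -2.74, -3.88]
    category_labels: [none, mild, middle, always]
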