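# IWPC warfarin dosing knowledge table.
#
# Both models are linear predictors of sqrt(weekly warfarin dose in mg);
# the predicted weekly dose is the square of the linear predictor.
# Covariates: age in decades, height in cm, weight in kg, race group,
# enzyme-inducer co-medication (carbamazepine/phenytoin/rifampin),
# amiodarone co-medication, and for the pharmacogenetic model the
# CYP2C9 diplotype and the VKORC1 -1639 G>A (rs9923231) genotype.
version: "IWPC-2009"
knowledge_ref: "International Warfarin Pharmacogenetics Consortium dosing algorithm"
pharmacogenetic:
  intercept: 5.6044
  age_decades: -0.2614
  height_cm: 0.0087
  weight_kg: 0.0128
  vkorc1_1639:
    GG: 0.0
    GA: -0.8677
    AA: -1.6974
    unknown: -0.4854
  cyp2c9:
    "*1/*1": 0.0
    "*1/*2": -0.5211
    "*1/*3": -0.9357
    "*2/*2": -1.0616
    "*2/*3": -1.9206
    "*3/*3": -2.3312
    unknown: -0.2188
  race:
    white: 0.0
    asian: -0.1092
    black_or_african_american: -0.2760
    mixed_or_missing: -0.1032
  enzyme_inducer: 1.1816
  amiodarone: -0.5503
clinical:
  intercept: 4.0376
  age_decades: -0.2546
  height_cm: 0.0118
  weight_kg: 0.0134
  race:
    white: 0.0
    asian: -0.6752
    black_or_african_american: 0.4060
    mixed_or_missing: 0.0443
  enzyme_inducer: 1.2799
  amiodarone: -0.5695
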