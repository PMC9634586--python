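# Default BZRA registry.
#
# dme_per_mg: diazepam-milligram-equivalents per mg of drug.  Anchored so that
#   0.5 mg clonazepam = 10 DME, 20 mg zolpidem = 10 DME, 1 mg lorazepam = 10 DME
#   and diazepam is the identity (1 mg = 1 DME).  Remaining factors follow the
#   Ashton equivalence table (doses approximately equivalent to 10 mg diazepam).
# ddd_mg: WHO ATC/DDD index defined daily dose, oral route (eszopiclone has no
#   WHO DDD; the customary 3 mg maintenance dose is used).
# indications: illustrative ICD-10 stems for the approved indications of each
#   drug; site-specific formularies should override this section.
provenance: >
  DME factors: anchored equivalences (clonazepam 20, zolpidem 0.5,
  lorazepam 10, diazepam 1 DME/mg) completed from the Ashton benzodiazepine
  equivalence table. DDD values: WHO ATC/DDD index 2024 (oral).
drugs:
  alprazolam:  {atc_code: N05BA12, drug_class: BZD,    dme_per_mg: 20.0,  ddd_mg: 1.0}
  estazolam:   {atc_code: N05CD04, drug_class: BZD,    dme_per_mg: 10.0,  ddd_mg: 3.0}
  lorazepam:   {atc_code: N05BA06, drug_class: BZD,    dme_per_mg: 10.0,  ddd_mg: 2.5}
  oxazepam:    {atc_code: N05BA04, drug_class: BZD,    dme_per_mg: 0.5,   ddd_mg: 50.0}
  midazolam:   {atc_code: N05CD08, drug_class: BZD,    dme_per_mg: 1.33,  ddd_mg: 15.0}
  diazepam:    {atc_code: N05BA01, drug_class: BZD,    dme_per_mg: 1.0,   ddd_mg: 10.0}
  clonazepam:  {atc_code: N03AE01, drug_class: BZD,    dme_per_mg: 20.0,  ddd_mg: 8.0}
  nitrazepam:  {atc_code: N05CD02, drug_class: BZD,    dme_per_mg: 1.0,   ddd_mg: 5.0}
  zolpidem:    {atc_code: N05CF02, drug_class: Z_DRUG, dme_per_mg: 0.5,   ddd_mg: 10.0}
  zopiclone:   {atc_code: N05CF01, drug_class: Z_DRUG, dme_per_mg: 0.67,  ddd_mg: 7.5}
  eszopiclone: {atc_code: N05CF04, drug_class: Z_DRUG, dme_per_mg: 3.33,  ddd_mg: 3.0}
  zaleplon:    {atc_code: N05CF03, drug_class: Z_DRUG, dme_per_mg: 0.5,   ddd_mg: 10.0}
indications:
  alprazolam:  [F40, F41]
  estazolam:   [G47]
  lorazepam:   [F40, F41]
  oxazepam:    [F40, F41]
  midazolam:   [G47]
  diazepam:    [F40, F41, G40, G41]
  clonazepam:  [G40, G41]
  nitrazepam:  [G40, G47]
  zolpidem:    [G47]
  zopiclone:   [G47]
  eszopiclone: [G47]
  zaleplon:    [G47]
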