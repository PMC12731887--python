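{
  "n": 426,
  "age": {"mean": 47.30, "sd": 11.27, "min": 19, "max": 67},
  "stage_counts": {"I": 44, "II": 173, "III": 168, "IV": 41},
  "education_counts": {
    "junior_secondary_or_less": 218,
    "high_school_or_junior_college": 140,
    "bachelor_or_more": 68
  },
  "marital_counts": {"married": 382, "unmarried_divorced_widowed": 44},
  "occupation_counts": {"in_service": 350, "no_occupation": 34, "retirement": 42},
  "income_counts": {"lt_3000": 134, "3000_5999": 141, "ge_6000": 151},
  "recruited": 450,
  "dropouts_t2": 24
}
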