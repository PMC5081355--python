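# Default code-set configuration.
#
# Only mm_diagnosis is authoritative (ICD-9-CM 203.0x, the multiple-myeloma
# family).  Every other list below is a PLACEHOLDER chosen so the synthetic
# generator and the test suite have concrete codes to work with; replace
# them with clinically curated lists before running on real claims.
#
# Each set uses a single coding system.  Patterns may end in a run of 'x'
# wildcards; dots are optional and ignored.

mm_diagnosis:
  system: ICD9DX
  patterns: ["203.0x"]

chemotherapy:           # PLACEHOLDER: chemotherapy administration procedures
  system: CPT4
  patterns: ["9640x", "9641x", "9642x"]

stem_cell_transplant:   # PLACEHOLDER
  system: CPT4
  patterns: ["38240", "38241"]

# --- the eight diagnostic-test sets (PLACEHOLDER lists) ---
protein_electrophoresis:
  system: CPT4
  patterns: ["84165", "84166", "86334", "86335"]
quantitative_immunoglobulin:
  system: CPT4
  patterns: ["82784", "82785"]
serum_free_light_chain:
  system: CPT4
  patterns: ["83883"]
serum_albumin:
  system: CPT4
  patterns: ["82040"]
beta2_microglobulin:
  system: CPT4
  patterns: ["82232"]
bone_marrow:
  system: CPT4
  patterns: ["38220", "38221", "85097"]
skeletal_survey:
  system: CPT4
  patterns: ["77074", "77075"]
ldh:
  system: CPT4
  patterns: ["83615"]

# --- treatments (PLACEHOLDER lists) ---
corticosteroid:
  system: NDC
  patterns: ["000540001xx"]
bisphosphonate:
  system: NDC
  patterns: ["000690002xx"]
anemia_treatment:
  system: CPT4
  patterns: ["36430"]

# --- symptom / comorbidity diagnosis sets (PLACEHOLDER lists) ---
monoclonal_gammopathy:
  system: ICD9DX
  patterns: ["273.1"]
other_malignancy:
  system: ICD9DX
  patterns: ["199.x"]
anemia_diagnosis:
  system: ICD9DX
  patterns: ["285.x"]
osteoporosis_diagnosis:
  system: ICD9DX
  patterns: ["733.0x"]
skeletal_related_event:
  system: ICD9DX
  patterns: ["733.1x"]
bone_pain_lesion:
  system: ICD9DX
  patterns: ["733.90"]
fatigue:
  system: ICD9DX
  patterns: ["780.7x"]
shortness_of_breath:
  system: ICD9DX
  patterns: ["786.0x"]
chest_pain:
  system: ICD9DX
  patterns: ["786.5x"]
peripheral_neuropathy:
  system: ICD9DX
  patterns: ["356.9"]
renal_failure:
  system: ICD9DX
  patterns: ["584.x", "585.x"]
hypercalcemia:
  system: ICD9DX
  patterns: ["275.42"]
pneumonia:
  system: ICD9DX
  patterns: ["486"]
herpes_zoster:
  system: ICD9DX
  patterns: ["053.x"]
urinary_tract_infection:
  system: ICD9DX
  patterns: ["599.0"]
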