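root: health_information
labels:
  health_information: Importance of health information on rare diseases
  medical_issues: Medical issues
  diagnosis: Diagnosis
  therapy: Therapy
  general_disease_pattern: General disease pattern
  research: Research
  current_studies: Current studies
  study_results: Study results
  registers: Registers
  social_help_offers: Social help offers
  psychosocial_counseling: Psychosocial counseling
  self_help_counseling: Self-help counseling
  sociolegal_advice: Sociolegal advice
  current_events: Current events
children:
  health_information:
    - medical_issues
    - research
    - social_help_offers
    - current_events
  medical_issues:
    - diagnosis
    - therapy
    - general_disease_pattern
  research:
    - current_studies
    - study_results
    - registers
  social_help_offers:
    - psychosocial_counseling
    - self_help_counseling
    - sociolegal_advice
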