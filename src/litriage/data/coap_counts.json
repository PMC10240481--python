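{
  "EPI: Case report": 241,
  "EPI: Case series": 350,
  "EPI: Case-control study": 74,
  "EPI: Cohort study": 246,
  "EPI: Cross-sectional study": 284,
  "EPI: Diagnostic study": 181,
  "EPI: Ecological study": 92,
  "EPI: Guidelines": 326,
  "EPI: Modelling study": 808,
  "EPI: Other": 130,
  "EPI: Outbreak or surveillance report": 133,
  "EPI: Qualitative study": 35,
  "EPI: Review": 725,
  "EPI: Trial": 40,
  "BASIC: Animal experiment": 43,
  "BASIC: Basic research review": 135,
  "BASIC: Biochemical/protein structure studies": 264,
  "BASIC: In vitro experiment": 85,
  "BASIC: Sequencing and phylogenetics": 241,
  "BASIC: Within-host modelling": 31,
  "OTHER: Other": 143,
  "OTHER: Comment, editorial, ..., non-original": 1758
}
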