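{
  "name": "COAP study-design taxonomy",
  "nodes": [
    {"id": "ORIGINAL", "name": "Original research", "level": "class", "parent": null},
    {"id": "NON-ORIGINAL", "name": "Commentaries, editorials, narrative reviews", "level": "class", "parent": null},
    {"id": "EPI", "name": "Epidemiologic study designs", "level": "subclass", "parent": "ORIGINAL"},
    {"id": "BASIC", "name": "Basic biological or laboratory-based research", "level": "subclass", "parent": "ORIGINAL"},
    {"id": "OTHER", "name": "Other types of articles", "level": "subclass", "parent": "NON-ORIGINAL"},
    {"id": "EPI: Case report", "name": "Case report", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Case series", "name": "Case series", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Case-control study", "name": "Case-control study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Cohort study", "name": "Cohort study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Cross-sectional study", "name": "Cross-sectional study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Diagnostic study", "name": "Diagnostic study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Ecological study", "name": "Ecological study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Guidelines", "name": "Guidelines", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Modelling study", "name": "Modelling study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Other", "name": "Other epidemiologic study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Outbreak or surveillance report", "name": "Outbreak or surveillance report", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Qualitative study", "name": "Qualitative study", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Review", "name": "Review", "level": "sub-subclass", "parent": "EPI"},
    {"id": "EPI: Trial", "name": "Trial", "level": "sub-subclass", "parent": "EPI"},
    {"id": "BASIC: Animal experiment", "name": "Animal experiment", "level": "sub-subclass", "parent": "BASIC"},
    {"id": "BASIC: Basic research review", "name": "Basic research review", "level": "sub-subclass", "parent": "BASIC"},
    {"id": "BASIC: Biochemical/protein structure studies", "name": "Biochemical/protein structure studies", "level": "sub-subclass", "parent": "BASIC"},
    {"id": "BASIC: In vitro experiment", "name": "In vitro experiment", "level": "sub-subclass", "parent": "BASIC"},
    {"id": "BASIC: Sequencing and phylogenetics", "name": "Sequencing and phylogenetics", "level": "sub-subclass", "parent": "BASIC"},
    {"id": "BASIC: Within-host modelling", "name": "Within-host modelling", "level": "sub-subclass", "parent": "BASIC"},
    {"id": "OTHER: Other", "name": "Other", "level": "sub-subclass", "parent": "OTHER"},
    {"id": "OTHER: Comment, editorial, ..., non-original", "name": "Comment, editorial, ..., non-original", "level": "sub-subclass", "parent": "OTHER"}
  ],
  "aliases": {
    "BASIC: Within-host modeling": "BASIC: Within-host modelling"
  }
}
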