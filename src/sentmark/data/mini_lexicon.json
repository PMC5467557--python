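{
  "we|studied": ["goal", "method"],
  "we|used": ["goal", "method"],
  "we|investigated": ["goal", "method"],
  "we|examined": ["goal", "method"],
  "we|aimed": ["goal"],
  "we|sought": ["goal"],
  "we|intended": ["goal"],
  "we|hypothesized": ["goal"],
  "study|aimed": ["goal"],
  "aims|were": ["goal"],
  "goal|was": ["goal"],
  "objective|was": ["goal"],
  "we|assessed": ["goal", "method"],
  "we|measured": ["method"],
  "we|recruited": ["method"],
  "we|performed": ["method"],
  "we|administered": ["method"],
  "we|applied": ["method"],
  "we|compared": ["method"],
  "we|analyzed": ["method"],
  "patients|underwent": ["method"],
  "patients|required": ["method"],
  "patients|completed": ["method"],
  "patients|performed": ["method"],
  "participants|asked": ["method"],
  "participants|completed": ["method"],
  "subjects|stimulated": ["method"],
  "subjects|underwent": ["method"],
  "images|acquired": ["method"],
  "mr images|acquired": ["method"],
  "time|acquired": ["method"],
  "examinations|registered": ["method"],
  "scans|obtained": ["method"],
  "data|collected": ["method"],
  "we|found": ["finding"],
  "we|observed": ["finding"],
  "results|show": ["finding"],
  "our results|show": ["finding"],
  "results|revealed": ["finding"],
  "analysis|revealed": ["finding"],
  "surface maps|revealed": ["finding"],
  "findings|suggest": ["finding"],
  "patients|showed": ["finding"],
  "scores|correlated": ["finding"],
  "atrophy|was": ["finding"],
  "differences|were": ["finding"]
}
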