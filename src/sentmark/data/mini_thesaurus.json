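{
  "study": ["investigate", "examine", "analyze", "explore"],
  "investigate": ["study", "examine", "explore"],
  "examine": ["study", "investigate", "inspect", "assess"],
  "analyze": ["study", "examine", "evaluate"],
  "use": ["employ", "utilize", "apply"],
  "employ": ["use", "utilize"],
  "utilize": ["use", "employ"],
  "apply": ["use", "employ"],
  "aim": ["intend", "seek", "target"],
  "intend": ["aim", "plan"],
  "seek": ["aim", "pursue"],
  "measure": ["quantify", "assess", "record"],
  "assess": ["evaluate", "measure", "examine"],
  "evaluate": ["assess", "measure", "analyze"],
  "show": ["demonstrate", "reveal", "indicate", "display"],
  "demonstrate": ["show", "reveal", "indicate"],
  "reveal": ["show", "demonstrate", "uncover", "indicate"],
  "indicate": ["show", "suggest", "demonstrate"],
  "suggest": ["indicate", "imply"],
  "find": ["observe", "detect", "discover"],
  "observe": ["find", "note", "detect"],
  "detect": ["find", "observe", "identify"],
  "identify": ["detect", "recognize"],
  "recruit": ["enroll", "enlist"],
  "enroll": ["recruit", "register"],
  "acquire": ["obtain", "collect", "get"],
  "obtain": ["acquire", "collect", "get"],
  "collect": ["acquire", "obtain", "gather"],
  "perform": ["conduct", "carry", "execute"],
  "conduct": ["perform", "carry"],
  "complete": ["finish", "perform"],
  "undergo": ["receive", "experience"],
  "correlate": ["associate", "relate"],
  "associate": ["correlate", "relate"],
  "compare": ["contrast"],
  "administer": ["give", "apply"],
  "patient": ["subject", "participant", "case"],
  "subject": ["patient", "participant"],
  "participant": ["patient", "subject", "volunteer"],
  "result": ["finding", "outcome"],
  "finding": ["result", "outcome"],
  "outcome": ["result", "finding"],
  "goal": ["aim", "objective", "purpose"],
  "objective": ["goal", "aim", "purpose"],
  "aims": ["goal", "objective"],
  "analysis": ["assessment", "evaluation"],
  "image": ["scan", "map"],
  "scan": ["image"],
  "score": ["rating", "measure"],
  "we": ["we"]
}
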