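# Demonstration gazetteer: neuropsychometric tests and neuroanatomy terms.
# One term per line; optional tab-separated concept id.
MoCA
MMSE
MDS-UPDRS
UPDRS
FTD
Alzheimer's disease
Parkinson's disease
Boston Naming Test
Trail Making Test
Stroop
hippocampus
amygdala
putamen
caudate nucleus
substantia nigra
prefrontal cortex
temporal lobe
parietal lobe
frontal lobe
entorhinal cortex
cerebellum
basal ganglia
grey matter
white matter
thalamus
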