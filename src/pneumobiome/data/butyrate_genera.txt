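# Default reference list of butyrate-producing genera (editable).
# One genus per line; lines starting with '#' are ignored.
# Curated from metagenomic surveys of the dominant butyrate-production
# pathways in the human gut; replace with a study-specific list as needed.
Anaerobutyricum
Anaerostipes
Anaerotruncus
Butyricicoccus
Butyricimonas
Butyrivibrio
Coprococcus
Eubacterium
Faecalibacterium
Flavonifractor
Intestinimonas
Odoribacter
Oscillibacter
Pseudoflavonifractor
Roseburia
Shuttleworthia
Subdoligranulum
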