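"""Published reference quantities used as fixed inputs.

These are reported study-level numbers for the arginylation-site
prediction protocol and the human/mouse reference proteomes; they enter
arithmetic consistency checks and proteome-scale extrapolations, never
model fitting.
"""

#: cross-validated AUC of the ensemble trained on literature + first array
AUC_LITERATURE_ARRAY2 = 0.74
#: cross-validated AUC of the ensemble trained on the final combined set
AUC_FINAL = 0.87

#: estimated fraction of potentially arginylated D/E residues, both species
PROTEOME_FRACTION = 0.03

#: counts of D and E residues in the human and mouse reference proteomes
HUMAN_DE_COUNT = 1_340_938
MOUSE_DE_COUNT = 1_125_895

#: D/E residues at protein position 1 or 2 (N-terminally exposed candidates)
HUMAN_NTERM_DE_COUNT = 3_146
MOUSE_NTERM_DE_COUNT = 2_680

#: proteins with evolutionarily conserved N-terminal MC / MD / ME starts
CONSERVED_NTERM_C = 62
CONSERVED_NTERM_D = 510
CONSERVED_NTERM_E = 913
CONSERVED_NTERM_TOTAL = CONSERVED_NTERM_C + CONSERVED_NTERM_D + CONSERVED_NTERM_E
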