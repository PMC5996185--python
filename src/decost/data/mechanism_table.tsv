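mechanism	value
Activator	1
Adduct	0.5
Agonist	1
Allosteric modulator	0
Antagonist	-1
Antibody	0
Binder	0
Chaperone	1
Chelator	0
Cleavage	-1
Cofactor	1
Component of	0
Cross-linking/alkylation	0
Incorporation into and destabilization	-1
Inducer	1
Inhibitor	-1
Inhibitor, competitive	-1
Inhibitory allosteric modulator	-1
Intercalation	0
Ligand	0
Metabolizer	0
Modulator	0
Multitarget	0
Negative modulator	-1
Neutralizer	0
Other	0
Other/unknown	0
Partial agonist	1
Partial antagonist	-1
Positive allosteric modulator	1
Potentiator	1
Product of	0
Reducer	-1
Stimulator	1
Suppressor	-1
Unknown	0
Other terms	0
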