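genus	family	gram
Escherichia	Enterobacteriaceae	negative
Salmonella	Enterobacteriaceae	negative
Klebsiella	Enterobacteriaceae	negative
Shigella	Enterobacteriaceae	negative
Enterobacter	Enterobacteriaceae	negative
Pseudomonas	Pseudomonadaceae	negative
Pseudoalteromonas	Pseudoalteromonadaceae	negative
Vibrio	Vibrionaceae	negative
Erwinia	Erwiniaceae	negative
Acinetobacter	Moraxellaceae	negative
Bacillus	Bacillaceae	positive
Staphylococcus	Staphylococcaceae	positive
Streptococcus	Streptococcaceae	positive
Enterococcus	Enterococcaceae	positive
Micrococcus	Micrococcaceae	positive
Microbacterium	Microbacteriaceae	positive
Mycobacterium	Mycobacteriaceae	positive
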