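family	outcome
16	causative
19	candidate_only
58	candidate_only
72	candidate_only
91	candidate_only
118	candidate_only
154	causative
207	causative
238	causative
241	candidate_only
346	causative
368	causative
400	none
439	causative
469	causative
481	candidate_only
512	candidate_only
528	candidate_only
549	candidate_only
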