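# Curation log for the bundled 98-taxon P8 restriction-site table.
# Each entry records a cell of the printed source table whose bundled value
# differs from the text as printed, with the reason for the change.
# Format: taxon <TAB> column <TAB> printed <TAB> curated <TAB> reason
Ancistrorhynchus cephalotes	VspI	120, 603, 120, 603	120,603	duplicated run removed (positions listed twice)
Christensonia vietnamica	TspDTI	27, 206, 226, 316, 372, 43027, 206, 226, 316, 372, 430	27,206,226,316,372,430	doubled run with a typographic join ("43027" = "430"+"27") resolved to the single list; corroborated by the identical printed list for Seidenfadenia mitrata, which the source text states shares all TspDTI sites with this taxon
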