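# Default P8 border anchor configuration.
#
# The P8 stem-loop has no printed, universally agreed flanking motifs; the
# conserved borders must be derived from published trnL group-I intron
# secondary-structure models for the taxa under study.  These defaults are
# the anchor pair used by this package's synthetic-sequence generator and
# serve as working placeholders: for real survey data, replace them with
# anchors derived from the structure literature for your group.
# Format: key <TAB> value
left_anchor	GTGGCGAAGCTCCGG
right_anchor	CCGGAGTCCTTGCGC
max_mismatches	0
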