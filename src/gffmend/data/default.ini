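; Default repair rules and naming patterns, loaded before any
; assembly-specific configuration. Assembly files override key-wise.

[GFF]
CONDITION_1 = [MULTILINE CDS]
CONDITION_2 = [LACKS_ID CDS make]
CONDITION_3 = [EXPECTATION cds hasSister exon force]
CONDITION_4 = [EXPECTATION cds hasParent mrna force]
CONDITION_5 = [EXPECTATION exon hasParent transcript|mrna|mirna|trna|ncrna|rrna force]
CONDITION_6 = [EXPECTATION mrna hasParent gene force]

[GENE_STABLE_IDS]
GFF = [SELF->ID/(.+)/]

[TRANSCRIPT_STABLE_IDS]
GFF = [SELF->ID/(.+)/]

[TRANSLATION_STABLE_IDS]
GFF = [SELF->ID/(.+)/]

[META]
ORGANISM = unclassified organism
TAXONOMY = Eukaryota
DIVISION = UNC
DATA_CLASS = STD
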