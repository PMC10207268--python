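# Named SMARTS patterns flagged by the post-generation filter.
# One pattern per line: <flag-name> <SMARTS>.  Lines starting with '#' are
# comments.  Strained small-ring alkenes and Bredt-rule bridgehead alkenes
# are detected by ring analysis in code, not by SMARTS.
acid_halide [CX3](=O)[F,Cl,Br,I]
disulfide [#16]-[#16]
peroxide [#8]-[#8]
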