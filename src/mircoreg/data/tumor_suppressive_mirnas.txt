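# Well-known tumor-suppressive miRNA families (13 entries;
# miR-15/16 is one family, miR-203/204/205 are three).
let-7
miR-15/16
miR-26
miR-29
miR-31
miR-34
miR-145
miR-200
miR-203
miR-204
miR-205
miR-223
miR-375
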