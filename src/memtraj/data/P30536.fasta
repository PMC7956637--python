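>P30536 TSPO_HUMAN translocator protein (18 kDa), canonical sequence M1-E169
MAPPWVPAMGFTLAPSLGCFVGSRFVHGEGLRWYAGLQKPSWHPPHWVLGPVWGTLYSAM
GYGSYLVWKELGGFTEKAVVPLGLYTGQLALNWAWPPIFFGARQMGWALVDLLLVSGAAA
ATTVAWYQVSPLAARLLYPYLAWLAFTTTLNYCVWRDNHGWHGGRRLPE
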