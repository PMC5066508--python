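>ancestral_core assembled 75-nt ancestral tRNA core
GCGGCCGTAGTCTAGCCTGGACTAGACCGCCGGGCTTGTAACCCGGCGGCCCCGGGTTCAAATCCCGGCGGCCGC
>ancestral_as5 5' acceptor stem (positions 1-7)
GCGGCCG
>ancestral_as3 3' acceptor stem (positions 69-75)
CGGCCGC
>ancestral_drem D-region acceptor-stem relic (positions 25-29)
GACCG
>ancestral_vloop V-loop acceptor-stem relic (positions 47-51)
TGGTC
>ancestral_d_micro D-arm microhelix, anticodon GCC (positions 8-24)
TAGTCTAGCCTGGACTA
>ancestral_ac_micro anticodon microhelix, placeholder anticodon TGT (positions 30-46)
CCGGGCTTGTAACCCGG
>ancestral_t_micro T-arm microhelix, anticodon CAA (positions 52-68)
CCGGGTTCAAATCCCGG
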