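; synthetic training set: 10 sites written from the 7-bp Helper consensus
; GCCGCCR (R=A/G), including two GCCGGCR variants so that the
; semi-palindromic YGCCGGCR word is callable on both strands.
; NOT the experimentally characterized functional-site alignment.
>helper_syn_01
GCCGCCA
>helper_syn_02
GCCGCCG
>helper_syn_03
GCCGCCA
>helper_syn_04
GCCGCCG
>helper_syn_05
GCCGCCA
>helper_syn_06
GCCGCCG
>helper_syn_07
GCCGCCA
>helper_syn_08
GCCGCCG
>helper_syn_09
GCCGGCA
>helper_syn_10
GCCGGCG
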