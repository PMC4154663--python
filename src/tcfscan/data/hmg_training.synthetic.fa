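; synthetic training set: 12 sites written from the 11-bp HMG consensus
; SCTTTGWWSWW (S=C/G, W=A/T) with one off-consensus position for realism.
; NOT the experimentally characterized functional-site alignment.
>hmg_syn_01
CCTTTGAACAA
>hmg_syn_02
GCTTTGAACAT
>hmg_syn_03
CCTTTGATCTA
>hmg_syn_04
CCTTTGATGTT
>hmg_syn_05
GCTTTGAAGTA
>hmg_syn_06
CCTTTGATCAT
>hmg_syn_07
GCTTTGTAGTA
>hmg_syn_08
CCTTTGTACTT
>hmg_syn_09
GCTTTATAGAA
>hmg_syn_10
CCTTTGTTCTT
>hmg_syn_11
GCTTTGTAGAA
>hmg_syn_12
CCTTTGTTGTT
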