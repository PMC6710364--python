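# Transcriptional core of naive B cell -> plasma cell differentiation.
# LPS stimulation phosphorylates AP-1; Bcl-6 passively represses AP-1 by
# binding it.  Blimp-1 is activated via AP-1 and mutually represses both
# Bcl-6 and Pax-5; Pax-5 and Bcl-6 are high in B cells and shut off by
# Blimp-1.
inputs: LPS
AP1, LPS & !Bcl6
Blimp1, AP1 & !Bcl6 & !Pax5
Pax5, !Blimp1
Bcl6, !Blimp1
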