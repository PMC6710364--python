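# NF-kB signaling core: microenvironmental TNFa stimulates IKK, which
# phosphorylates IkBa, freeing the p65_RelA dimer to translocate to the
# nucleus where it drives transcription of IkBa (tIkBa), closing the
# negative feedback loop.
inputs: TNFa
IKK, TNFa
p65_RelA, IKK & !IkBa
tIkBa, p65_RelA
IkBa, tIkBa
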