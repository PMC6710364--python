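# Three-node ring with a single (odd) inhibition: a negative feedback
# circuit, hence no fixed point under synchronous update.
A, !C
B, A
C, B
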