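# Two mutually repressing genes: the minimal bistable switch (a positive
# circuit with an even number of inhibitions).
A, !B
B, !A
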