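# IIS demo candidate list (daf-2 is deliberately absent: it is the linker)
daf-16
daf-3
peb-1
myo-2
daf-36
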