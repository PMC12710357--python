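((Symbiopectobacterium-C19,Symbiopectobacterium-C28),Symbiopectobacterium-C41,Symbiopectobacterium-C57,Symbiopectobacterium-C61);
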