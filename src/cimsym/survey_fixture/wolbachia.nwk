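(Wolbachia-C1,Wolbachia-C5,Wolbachia-C12-high,Wolbachia-C12-low,Wolbachia-C21-high,Wolbachia-C21-low,Wolbachia-C51-low,(Wolbachia-C66,(Wolbachia-C49,((Wolbachia-C56,Wolbachia-C57),((Wolbachia-C44,Wolbachia-C51-high),Wolbachia-C61)))));
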