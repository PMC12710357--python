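(C5,(C1,((C12,C21),((C19,C28),(C41,(C66,(C49,((C56,C57),((C44,C51),C61)))))))));
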