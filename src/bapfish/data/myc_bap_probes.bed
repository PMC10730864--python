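chr8	127335000	127735000	FIVE_PRIME_MYC
chr8	127935000	128335000	THREE_PRIME_MYC
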