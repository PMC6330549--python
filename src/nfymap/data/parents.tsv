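id	length
QQS	59
AtNF-YC4
HsNF-YC
GmNF-YC4-1
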