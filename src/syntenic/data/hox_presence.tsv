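gene	Pangasianodon	Danio
A1a	P	P
A2a	A	Ψ
A4a	P	P
A5a	A	P
A7a	A	Ψ
A10a	A	Ψ
A11a	A	P
B1a	P	P
B3b	P	A
B10a	A	P
C4b	P	A
C5b	P	A
C8b	A	A
C9a	P	A
C10b	A	A
D1a	P	A
D4b	A	A
D9b	A	A
D11b	A	A
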