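condition	copies	sem
no donor	329.48	13.62
AI-CTL	442.58	12.59
AI-100	357.23	16.65
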