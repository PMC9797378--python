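# 4-level toxicity scale: least to most toxic
labels:
  - not toxic
  - hard to say
  - toxic
  - very toxic
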