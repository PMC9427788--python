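"""Physical constants shared across modules."""

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314
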