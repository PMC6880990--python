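icd9,cui
331.0,C0002395
296.21,C0154409
296.31,C0154417
311,C0011570
299.00,C0004352
299.01,C0004352
377.30,C0029132
365.11,C0017612
365.9,C0017612
288.60,C0023508
800.00,C0037303
807.00,C0035522
345.90,C0014544
290.0,C0497327
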