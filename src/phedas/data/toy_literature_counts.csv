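# disease_count: 120000
phecode,pair_count
290.11,25000
313.3,18000
296.2,15000
290.1,9000
345,6000
377.3,2400
306.9,300
365,120
288.6,60
800,30
807,12
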