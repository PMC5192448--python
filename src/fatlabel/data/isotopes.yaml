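# Natural isotope abundances per element over mass offsets +0,+1,+2 u.
# Edit to model tracer purity or non-standard abundances.
C:
- 0.9893
- 0.0107
H:
- 0.999885
- 0.000115
O:
- 0.99757
- 0.00038
- 0.00205
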