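{
 "wall": "modiolar",
 "reference_A": 5.46,
 "reference_B": 3.17,
 "version": "mean-v1"
}
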