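{
 "spec": "three-group",
 "seed": 1,
 "sizes": [
  50,
  50,
  50
 ],
 "dichotomized": false
}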