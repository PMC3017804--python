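{
 "subdomain_spans": {
  "A": [
   1,
   28
  ],
  "B": [
   33,
   60
  ],
  "C": [
   65,
   100
  ],
  "D": [
   104,
   130
  ],
  "E": [
   134,
   158
  ]
 }
}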