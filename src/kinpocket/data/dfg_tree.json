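{
 "features": [
  "asa_d81",
  "yd",
  "yf"
 ],
 "tree": {
  "feature": "yd",
  "threshold": -1.1812,
  "left": {
   "class": "DFG-out"
  },
  "right": {
   "feature": "yd",
   "threshold": 1.3633,
   "left": {
    "class": "DFG-outlike"
   },
   "right": {
    "class": "DFG-in"
   }
  }
 }
}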