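{
 "assignment_radius": 1.5,
 "dfg_out_specific": [
  "O1",
  "O2"
 ],
 "centroids": {
  "I1": [
   6.266,
   -1.018,
   1.728
  ],
  "I2": [
   1.184,
   -4.763,
   3.862
  ],
  "I3": [
   0.23,
   -0.478,
   4.557
  ],
  "I4": [
   -1.521,
   -3.982,
   -1.052
  ],
  "I5": [
   -1.8,
   1.761,
   -0.531
  ],
  "I6": [
   1.989,
   2.239,
   3.254
  ],
  "I7": [
   4.995,
   2.541,
   -1.44
  ],
  "I8": [
   0.939,
   -5.416,
   -2.012
  ],
  "I9": [
   0.029,
   3.542,
   -3.158
  ],
  "I10": [
   5.955,
   4.469,
   0.455
  ],
  "I11": [
   6.787,
   2.174,
   3.326
  ],
  "O1": [
   -8.752,
   -7.5,
   -3.452
  ],
  "O2": [
   -7.192,
   -0.602,
   -1.785
  ]
 }
}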