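{
 "feature_names": [
  "density",
  "width",
  "length",
  "solidity",
  "surrounding_collagen_area"
 ],
 "classes": [
  "other",
  "vessel_or_duct"
 ],
 "nodes": {
  "children_left": [
   1,
   -1,
   3,
   4,
   5,
   -1,
   -1,
   -1,
   9,
   -1,
   -1
  ],
  "children_right": [
   2,
   -1,
   8,
   7,
   6,
   -1,
   -1,
   -1,
   10,
   -1,
   -1
  ],
  "feature": [
   4,
   -2,
   0,
   4,
   1,
   -2,
   -2,
   -2,
   4,
   -2,
   -2
  ],
  "threshold": [
   29.6783447265625,
   -2.0,
   5.5,
   72.8607177734375,
   6.764940023422241,
   -2.0,
   -2.0,
   -2.0,
   113.9068603515625,
   -2.0,
   -2.0
  ],
  "leaf_class": [
   1,
   0,
   1,
   1,
   1,
   1,
   1,
   1,
   1,
   0,
   1
  ]
 },
 "meta": {
  "criterion": "gini",
  "max_depth": 4,
  "min_samples_leaf": 5,
  "seed": 0
 }
}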