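{
 "feature_names": [
  "n_holes",
  "total_hole_area",
  "max_hole_area",
  "collagen_area"
 ],
 "classes": [
  "central_vein",
  "portal_tract"
 ],
 "nodes": {
  "children_left": [
   1,
   -1,
   -1
  ],
  "children_right": [
   2,
   -1,
   -1
  ],
  "feature": [
   0,
   -2,
   -2
  ],
  "threshold": [
   1.5,
   -2.0,
   -2.0
  ],
  "leaf_class": [
   1,
   0,
   1
  ]
 },
 "meta": {
  "criterion": "gini",
  "max_depth": 4,
  "min_samples_leaf": 3,
  "seed": 0
 }
}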