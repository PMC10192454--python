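{
 "gx1_self": {
  "n_rows": 28,
  "column_sums": {
   "pod_set_pct": 789.8,
   "pseudo_pod_set_pct": 235.5,
   "number_of_pods": 331.0,
   "pod_weight": 3485.9,
   "nuts_per_pod": 196.3,
   "weight_unpeeled": 1980.6,
   "weight_peeled": 1390.6,
   "outturn": 1914.0,
   "brix": 324.9,
   "potential_alcohol": 190.8,
   "firmness": 380.1
  }
 },
 "mx2_self": {
  "n_rows": 27,
  "column_sums": {
   "pod_set_pct": 803.7,
   "pseudo_pod_set_pct": 227.6,
   "number_of_pods": 471.8,
   "pod_weight": 4625.1,
   "nuts_per_pod": 151.8,
   "weight_unpeeled": 1396.6,
   "weight_peeled": 1094.8,
   "outturn": 2094.3,
   "brix": 340.4,
   "potential_alcohol": 193.6,
   "firmness": 389.1
  }
 }
}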