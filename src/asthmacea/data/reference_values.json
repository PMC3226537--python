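{
  "expectations": {
    "multifaceted": {"expected_cost": 539.49, "p_asthma_avoided": 0.93191, "n": 259},
    "unifaceted": {"expected_cost": 445.19, "p_asthma_avoided": 0.92610, "n": 53},
    "current": {"expected_cost": 302.30, "p_asthma_avoided": 0.96494, "n": null}
  },
  "group_sizes": {
    "candidate_pfh": 443,
    "evaluable_pfh": 324,
    "multifaceted": 259,
    "unifaceted": 53,
    "pfh_control": 12
  },
  "mixture_weights": {"w_pfh": 0.20, "w_nfh": 0.80},
  "threshold_range": {"lambda_min": 0, "lambda_max": 70000}
}
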