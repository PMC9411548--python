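{
  "M": 48,
  "zones": [
    [
      36,
      14
    ],
    [
      39,
      45
    ],
    [
      26,
      40
    ],
    [
      22,
      7
    ],
    [
      25,
      3
    ],
    [
      43,
      45
    ],
    [
      10,
      18
    ],
    [
      27,
      1
    ],
    [
      45,
      35
    ],
    [
      15,
      28
    ],
    [
      28,
      44
    ],
    [
      5,
      43
    ]
  ],
  "topology": "bounded",
  "spawn": {
    "shape": "square",
    "size": 7,
    "layout": "tile",
    "spacing": 1
  },
  "params": {
    "n_swaps": 1000,
    "s_max": 3,
    "iteration_cap": 10000000,
    "no_change_threshold": 1000000,
    "seed": null,
    "walk_policy": "stable",
    "membrane_budget": 1000,
    "walk_leak": 0.15
  },
  "seed": 9,
  "obstacle": "obstacle_map.txt"
}
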