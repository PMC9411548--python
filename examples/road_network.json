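{
  "M": 80,
  "zones": [
    [
      72,
      25
    ],
    [
      8,
      48
    ],
    [
      52,
      21
    ],
    [
      41,
      62
    ],
    [
      17,
      50
    ],
    [
      70,
      28
    ],
    [
      37,
      64
    ],
    [
      10,
      52
    ],
    [
      39,
      52
    ],
    [
      3,
      37
    ],
    [
      38,
      61
    ],
    [
      54,
      29
    ],
    [
      61,
      61
    ],
    [
      2,
      35
    ],
    [
      59,
      28
    ],
    [
      62,
      44
    ],
    [
      37,
      52
    ],
    [
      59,
      20
    ],
    [
      25,
      56
    ],
    [
      49,
      44
    ],
    [
      76,
      20
    ],
    [
      67,
      31
    ],
    [
      53,
      41
    ],
    [
      3,
      2
    ],
    [
      27,
      29
    ],
    [
      42,
      31
    ],
    [
      13,
      41
    ],
    [
      57,
      49
    ],
    [
      68,
      29
    ],
    [
      2,
      9
    ],
    [
      63,
      76
    ],
    [
      44,
      11
    ],
    [
      61,
      23
    ],
    [
      38,
      43
    ],
    [
      49,
      32
    ],
    [
      60,
      69
    ],
    [
      55,
      34
    ],
    [
      63,
      26
    ],
    [
      17,
      25
    ],
    [
      49,
      61
    ]
  ],
  "topology": "bounded",
  "spawn": {
    "shape": "diamond",
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
  "seed": 0
}
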