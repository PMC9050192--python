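{
  "grid_size": 7,
  "cell_features": 12,
  "n_observation_channels": 588,
  "channel_order": "cell-major: index = (row*7 + col)*12 + feature",
  "frames": {
    "relative": "cell = (3+dr, 3+dc), offset from the observer; goal clipped, walls/agents dropped beyond +-3",
    "absolute": "cell = grid position"
  },
  "features": {
    "0": "wall present (relative frame)",
    "1": "observer's own goal (relative frame, clipped)",
    "2": "reserved",
    "3": "reserved",
    "4": "agent 0 occupies cell (relative frame; absolute for the observer itself)",
    "5": "agent 1 occupies cell (relative frame; absolute for the observer itself)",
    "6": "agent 2 occupies cell (relative frame; absolute for the observer itself)",
    "7": "agent 3 occupies cell (relative frame; absolute for the observer itself)",
    "8": "agent 4 occupies cell (relative frame; absolute for the observer itself)",
    "9": "agent 5 occupies cell (relative frame; absolute for the observer itself)",
    "10": "agent 6 occupies cell (relative frame; absolute for the observer itself)",
    "11": "agent 7 occupies cell (relative frame; absolute for the observer itself)"
  },
  "style_channels": {
    "count": 18,
    "populations": {
      "reckless": 0,
      "experienced": 1,
      "cautious": 2
    },
    "neurons_per_population": 6
  },
  "action_order": [
    "up",
    "down",
    "left",
    "right",
    "stay"
  ]
}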