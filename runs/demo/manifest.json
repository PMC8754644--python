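{
  "version": "0.1.0",
  "python": "3.11.15",
  "config_hash": "52e42e78a2e6",
  "seed": 7,
  "shuffle_seed": 0,
  "stages": {
    "segment": {
      "n_labels_mean": 30.0
    },
    "track": {
      "n_tracks": 30
    },
    "quantify": {
      "n_trajectories": 30,
      "n_invalid_fits": 297
    },
    "callbursts": {
      "threshold": 527.467676248524,
      "n_bursts": 33
    },
    "reconstruct": {
      "n_nuclei": 30
    }
  }
}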