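{
  "version": 1,
  "description": "Canonical ground truth for the four-region visual imagery network (order OCC, FG, IPS, IFG; row = target, column = source). Text-anchored values: baseline OCC->IPS coupling 0.05 Hz; perception-on OCC->IPS total 0.94 Hz; imagery more than tripling the baseline IFG->OCC coupling; vividness acting only on top-down coupling to OCC (IPS->OCC toward excitation, FG->OCC toward inhibition) and on the OCC self-connection (disinhibition); no bottom-up imagery modulation. All other magnitudes are transcribed from figure - approximate: package choices respecting the published sign/significance pattern, sized so the system keeps a comfortable stability margin under between-subject variation.",
  "nodes": ["OCC", "FG", "IPS", "IFG"],
  "inputs": ["perception", "imagery", "vividness"],
  "A": [
    [0.0, -0.12, -0.18, 0.08],
    [0.22, 0.0, 0.08, 0.06],
    [0.05, 0.1, 0.0, 0.08],
    [0.08, 0.08, 0.1, 0.0]
  ],
  "self_log": [0.35, 0.35, 0.35, 0.35],
  "B": {
    "perception": [
      [0.0, -0.08, -0.25, 0.1],
      [0.18, 0.0, 0.04, 0.0],
      [0.89, 0.04, 0.0, 0.04],
      [0.08, 0.1, 0.08, 0.0]
    ],
    "imagery": [
      [0.0, 0.04, 0.0, 0.22],
      [0.0, 0.0, 0.04, 0.1],
      [0.0, 0.0, 0.0, 0.06],
      [0.0, 0.0, 0.0, 0.0]
    ],
    "vividness": [
      [-0.15, -0.1, 0.2, 0.0],
      [0.0, 0.0, 0.0, 0.0],
      [0.0, 0.0, 0.0, 0.0],
      [0.0, 0.0, 0.0, 0.0]
    ]
  },
  "C": [
    [0.4, 0.0, 0.0],
    [0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0],
    [0.0, 0.3, 0.0]
  ],
  "imagery_drive_occ": 0.1,
  "vividness_distribution": [0.0879, 0.2085, 0.351, 0.3528],
  "between_subject_sd": 0.1,
  "noise_sd": 1.0,
  "tr": 2.0
}
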