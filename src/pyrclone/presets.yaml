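# Simulator presets (version 1).  Parameter values are this package's own
# choices for an experiment-like synthetic regime; layer vectors are in
# generation order (VI, V, IV, II/III).
#
# "two_type": a majority type producing larger translaminar clones (size mode
# near eight) and a minority type producing small superficial-biased clones
# (size mode near four); interruption yields a slight superficial/deep
# anti-correlation.
two_type:
  n_progenitors: 100
  n_repeats: 100
  size_filter: [3, 12]
  types:
    - fraction: 0.7
      m: [3, 3, 3, 4]
      p: [0.95, 0.95, 0.95, 0.95]
      q: 0.06
    - fraction: 0.3
      m: [1, 1, 2, 3]
      p: [0.0, 0.0, 0.95, 0.95]
      q: 0.05
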