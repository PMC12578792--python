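# Channel adjacency for cluster formation, as an undirected edge list over
# 0-based channel indices. Derived from an illustrative 2 x 22-channel optode
# layout (two devices, one per hemisphere; channels chained along the strip
# with short cross-links). Real studies derive this from optode geometry.
n_channels: 44
edges:
  # left device: chain 0..21 plus local cross links
  - [0, 1]
  - [1, 2]
  - [2, 3]
  - [3, 4]
  - [4, 5]
  - [5, 6]
  - [6, 7]
  - [7, 8]
  - [8, 9]
  - [9, 10]
  - [10, 11]
  - [11, 12]
  - [12, 13]
  - [13, 14]
  - [14, 15]
  - [15, 16]
  - [16, 17]
  - [17, 18]
  - [18, 19]
  - [19, 20]
  - [20, 21]
  - [4, 6]
  - [5, 7]
  - [8, 10]
  - [9, 11]
  - [10, 12]
  # right device: chain 22..43 plus local cross links
  - [22, 23]
  - [23, 24]
  - [24, 25]
  - [25, 26]
  - [26, 27]
  - [27, 28]
  - [28, 29]
  - [29, 30]
  - [30, 31]
  - [31, 32]
  - [32, 33]
  - [33, 34]
  - [34, 35]
  - [35, 36]
  - [36, 37]
  - [37, 38]
  - [38, 39]
  - [39, 40]
  - [40, 41]
  - [41, 42]
  - [42, 43]
  - [26, 28]
  - [27, 29]
  - [30, 32]
  - [31, 33]
  - [32, 34]
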