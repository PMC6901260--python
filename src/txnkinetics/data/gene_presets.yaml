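# Default reporter-gene geometries for the tandem-array constructs.
#
# The constructs are beta-globin-derived mini-genes carried on a stably
# integrated multi-copy array: E3 has 3 exons / 2 introns, E6 has 6 exons /
# 5 introns, and both end in a 3'UTR with 18 MS2 stem-loop repeats placed
# downstream of the last intron.  Exact segment lengths of the constructs are
# not published; these defaults use a mini-gene-like scale (exons 300 bp,
# introns 400 bp, 1200 bp MS2 cassette) and are fully overridable.  Every
# quantitative property computed by the package is stated relative to the
# geometry actually used, never to these numbers.
E3:
  length_bp: 3100
  exons: [[0, 300], [700, 1000], [1400, 1700]]
  introns: [[300, 700], [1000, 1400]]
  ms2_region: [1700, 2900]
  n_ms2_repeats: 18
  exon_probe: [0, 300]
  intron_probe_indices: [0, 1]
  n_copies: 20
E6:
  length_bp: 5200
  exons: [[0, 300], [700, 1000], [1400, 1700], [2100, 2400], [2800, 3100], [3500, 3800]]
  introns: [[300, 700], [1000, 1400], [1700, 2100], [2400, 2800], [3100, 3500]]
  ms2_region: [3800, 5000]
  n_ms2_repeats: 18
  exon_probe: [0, 300]
  intron_probe_indices: [0, 1, 2, 3, 4]
  n_copies: 20
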