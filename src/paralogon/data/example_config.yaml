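# Bundled synthetic example: two whole-genome duplications on the root
# branch, 60 ancestral families on 4 chromosomes, stochastic loss, a tandem
# duplication of the cassette family, a translocation in one lineage, and a
# third (teleost-like) duplication in another. Seed 42.
seed: 42
output_dir: paralogon_out
scoring:
  matrix: blosum62
  gap_open: 10.0
  gap_extend: 0.20
bootstrap_replicates: 100
min_chromosomes: 3
max_align_families: 4
reference_species: birdlike
# the paralogon under study: the four descendants of ancestral chromosome 1
candidate_chromosomes: [chr1, chr1-2Ra, chr1-2Rb, chr1-2Ra-2Rb]
motif:
  pattern: "[YF]GGF"
  max_mismatch: 0
simulation:
  n_chromosomes: 4
  families_per_chromosome: 15
  sequence_length: 120
  retention_prob: 0.6
  cassette:
    pattern: YGGFM
    copies: 7
    families: [fam000]
    protected: true
  tree:
    name: root
    events:
      - {kind: wgd, label: 2Ra}
      - {kind: local_dup, gene_id: fam000.0}
      - {kind: wgd, label: 2Rb}
      - {kind: loss, retention: 0.6}
    length: 0.05
    children:
      - name: tetrapods
        length: 0.05
        children:
          - name: mammallike
            length: 0.10
            events:
              - {kind: translocation, source: chr1, interval: [0, 3000000], target: chr2}
          - name: birdlike
            length: 0.10
      - name: teleosts
        length: 0.05
        children:
          - name: fishlike
            length: 0.10
            events:
              - {kind: wgd, label: 3R}
          - name: fishlike2
            length: 0.10
scenario:
  observed:
    counts: [1, 2, 1, 0]
    adjacent: [false, true, false, false]
  constraints:
    - before: LOCAL
      after: WGD2
      note: duplicate pair already present in a lineage that branched before the second doubling
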