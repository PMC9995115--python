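# Packaged toy TRB-like recombination model.
#
# V suffixes are codon-aligned 15-nt 3' junction contributions beginning with
# the conserved Cys codon; J prefixes are codon-aligned 18-nt 5' contributions
# ending on a Phe codon, mimicking human TRBV/TRBJ CDR3 anchors. Usage is
# near-uniform with mild skew; deletions 0-4 nt, insertions 0-10 nt with a
# GC-biased i.i.d. nucleotide law (N-addition bias).
name: toy-trb-v1
v_segments:
  - {name: TRBV-A, suffix: TGTGCCAGCAGCTTG, prob: 0.20}   # CASSL
  - {name: TRBV-B, suffix: TGCGCCAGCAGACCG, prob: 0.16}   # CASRP
  - {name: TRBV-C, suffix: TGCAGTGCTAGAGAT, prob: 0.14}   # CSARD
  - {name: TRBV-D, suffix: TGTGCCTGGAGTGTA, prob: 0.12}   # CAWSV
  - {name: TRBV-E, suffix: TGTGCCAGCACTCCC, prob: 0.11}   # CASTP
  - {name: TRBV-F, suffix: TGCAGCGTTGGAACA, prob: 0.10}   # CSVGT
  - {name: TRBV-G, suffix: TGTGCCAGTGGGCTA, prob: 0.09}   # CASGL
  - {name: TRBV-H, suffix: TGTGCCATCAGTGAA, prob: 0.08}   # CAISE
j_segments:
  - {name: TRBJ-A, prefix: AATACTGAAGCTTTCTTT, prob: 0.22}  # NTEAFF
  - {name: TRBJ-B, prefix: TCCTACGAGCAGTACTTC, prob: 0.18}  # SYEQYF
  - {name: TRBJ-C, prefix: TATTACGGCTACACCTTC, prob: 0.17}  # YYGYTF
  - {name: TRBJ-D, prefix: AATCAGCCCCAGCATTTT, prob: 0.16}  # NQPQHF
  - {name: TRBJ-E, prefix: CAAGAGACCCAGTACTTT, prob: 0.15}  # QETQYF
  - {name: TRBJ-F, prefix: GGAAACACCATATATTTT, prob: 0.12}  # GNTIYF
v_deletions: [0.30, 0.25, 0.20, 0.15, 0.10]
j_deletions: [0.30, 0.25, 0.20, 0.15, 0.10]
insertion_lengths: [0.03, 0.06, 0.09, 0.12, 0.14, 0.14, 0.12, 0.10, 0.08, 0.07, 0.05]
insertion_nt: {A: 0.22, C: 0.28, G: 0.28, T: 0.22}
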