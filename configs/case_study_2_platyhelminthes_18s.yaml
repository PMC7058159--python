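# Replication configuration: Platyhelminthes 18S rRNA case study.
#
# A flatworm 18S dataset whose full and base trees both conflict with the
# modern consensus (monophyletic Platyhelminthes within Lophotrochozoa) —
# a deliberate stress test of the canary approach under an inaccurate base
# tree. All 15 flatworm (Platyhelminthes + Catenulida) sequences are the
# sequences of interest; each checking dataset holds 16 species, each
# canary-checking dataset 17. In the published analysis Discocelis tigrina
# is the single canary, Planocera the single nonproblematic noncanary, and
# the two-flatworm minimal tree recovers Platyhelminthes and
# Lophotrochozoa.
#
# The alignment is external data and is not bundled.

alignment: ""            # path to the aligned 18S FASTA (18 sequences)
format: fasta
alphabet: nucleotide
interest: ""             # path to a file listing the 15 flatworm sequence ids

engine:
  engine: internal
  model:
    kind: JC69
  nni_max_rounds: 50
  seed: 0

comp:
  n_sims: 99
  seed: 0
  alpha: 0.05

recompute_full: false
outdir: out/case_study_2
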