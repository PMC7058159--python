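# Replication configuration: Ecdysozoa 18S rRNA case study.
#
# The 18S rRNA dataset in which increased nematode sampling resolved a
# classic long-branch attraction artifact. The three nematode sequences
# are the sequences of interest; each checking dataset therefore holds
# 46 sequences (45 base + 1). In the published analysis two nematodes
# (Caenorhabditis, Trichuris) emerge as canaries and Strongyloides as
# potentially problematic; the minimal tree excluding Strongyloides
# recovers a monophyletic Ecdysozoa.
#
# The alignment is external data and is not bundled: obtain the aligned
# 18S matrix and fill in the paths below.

alignment: ""            # path to the aligned 18S FASTA (48 sequences)
format: fasta
alphabet: nucleotide
interest: ""             # path to a file listing the 3 nematode sequence ids

engine:
  engine: internal       # the original analysis used PhyML under JC69;
                         # use the external adapter to reproduce it exactly:
                         # engine: external
                         # external_command_template: "phyml-wrapper {alignment_phylip} {out_newick}"
  model:
    kind: JC69           # deliberately simple, matching the original studies
  nni_max_rounds: 50
  seed: 0

comp:
  n_sims: 99
  seed: 0
  alpha: 0.05

recompute_full: false
outdir: out/case_study_1
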