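# Replication configuration: the long-branch-attraction simulation study.
#
# Fifty datasets of 49 sequences x 1,968 nucleotides simulated under the
# REV (= GTR) model on the Ecdysozoa 18S tree, with the two long-branched
# nematode pendants (Strongyloides, Caenorhabditis) further elongated "by
# 250%" — implemented as x2.5 and configurable below; after elongation
# those pendants are ~10x the next longest branches (logged as a
# diagnostic). Analysis deliberately uses JC69 to mis-specify the model
# and provoke incorrect topologies. Replicates whose standard analysis is
# already correct, or where no canary / only canaries are found, are "not
# relevant" and excluded from the success rate. Success means recovering a
# monophyletic Nematoda as a member of the non-arthropod Ecdysozoa,
# formalized below through the allowed_sisters mechanism (edit the taxon
# lists to match your tree's labels).
#
# Note: the published description gives both 1,968 and 1,956 for the
# alignment length; this configuration uses the printed replicate length
# 1,968. The generating tree must come from the external Ecdysozoa 18S
# data (or the study's supplementary files) and is not bundled. Scoring
# pre-existing replicate alignments:
#   canary simulate --config this.yaml --outdir out/ --replicates-dir <dir>

tree: ""                 # path to the generating tree (Newick, 49 taxa,
                         # branch lengths in substitutions/site)
seq_length: 1968
n_replicates: 50
seed: 0

model:                   # simulation model (REV = GTR)
  kind: GTR
  # state_freqs / exchangeabilities: fill in the fitted values, or leave
  # the defaults to re-estimate from data with the internal engine
  gamma_shape: 0.5

elongate:                # "increased by 250%" -> x2.5 (configurable)
  Strongyloides: 2.5
  Caenorhabditis: 2.5

interest: []             # the nematode sequence ids

constraints:
  - clade: []            # all nematode taxa (monophyletic Nematoda)
    allowed_sisters: []  # the non-arthropod ecdysozoan taxa

engine:                  # analysis model (deliberately mis-specified)
  engine: internal
  model:
    kind: JC69
  seed: 0

comp:
  n_sims: 99
  alpha: 0.05
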