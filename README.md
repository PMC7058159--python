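# canaryseq

Canary-sequence screening of unstable and problematic sequences in
single-gene phylogenies.

Single-gene alignments are short, carry limited phylogenetic signal, and
cannot support the parameter-rich models used to suppress reconstruction
artifacts in phylogenomic supermatrices. Gene trees — opsins, 18S rRNA,
and other deep gene families — are therefore especially prone to
long-branch attraction and compositional artifacts, and to "problematic
sequences": sequences too poor in signal to be placed robustly under the
model at hand, which distort the relationships of everything around them.

`canaryseq` implements the canary-sequence approach for detecting and
removing such sequences, together with the simulation machinery used to
validate it. The idea mirrors the miner's canary: some sequences are
*unstable* — they wander between analyses — yet *harmless*: removing them
leaves all other relationships intact, and their composition is
unremarkable. These canaries are exquisitely sensitive to the presence of
problematic sequences, which attract them. The pipeline uses them as
indicators, and finally prunes the sequences that perturb them.

## The classification pipeline

Given a full alignment and a designated set of **sequences of interest**
(e.g. all nonbilaterian members of a gene family), with the **base
dataset** defined as everything else:

1. Infer the **base tree** and the **full tree**.
2. For each sequence of interest *s*, infer the **checking tree** from
   base + *s* alone.
3. If the checking tree minus *s* is not isomorphic to the base tree
   (Robinson–Foulds distance > 0 on the shared leaves), *s* perturbs the
   base relationships → **noncanary** pool.
4. Otherwise test *s* for compositional homogeneity (a parametric
   bootstrap of the per-sequence L1 deviation from pooled composition,
   simulated on the fitted tree and model). Heterogeneous → noncanary
   pool, irrespective of placement. Homogeneous and *placed differently*
   in the checking and full trees → **canary**. Homogeneous and placed
   identically → **stable**.
5. Canaries are added to the base dataset (the **canary dataset**) and the
   **canary tree** is inferred; stable sequences join the noncanary pool.
6. Each noncanary sequence *q* is added, alone, to the canary dataset; if
   the resulting **canary-checking tree** minus *q* is isomorphic to the
   canary tree, *q* is **nonproblematic**, otherwise **potentially
   problematic** (it moves the canaries) and is excluded.
7. The **minimal dataset** — base + canaries + nonproblematic sequences —
   yields the **minimal tree**, the pipeline's final product.
8. If no canaries are found, the minimal dataset is base + stable
   sequences instead.

"Position" is formalized as the unordered collection of leaf sets of the
subtrees at a leaf's attachment node; "isomorphic" as RF distance zero.
Every comparison is topological and unrooted.

The package also provides the internal maximum-likelihood engine used for
all of this (JC69/GTR+Γ for nucleotides, Poisson/LG+Γ for proteins;
neighbor joining → branch-length optimization → NNI search, fully
deterministic), an adapter for external engines such as PhyML or
PhyloBayes, a sequence simulator with terminal-branch elongation for
long-branch-attraction experiments, and engineered test fixtures with
known expected verdicts.

## Worked example

Generate an engineered long-branch-attraction fixture — ten well-behaved
taxa, one signal-eroded weak sequence (`CNRY`, 85% of its sites masked)
and one fast-evolving, compositionally biased sequence (`LBAX`) that
captures the weak one — and run the pipeline on it:

```bash
canary fixtures --scenario canary_lba --n-taxa 12 --seq-length 1000 \
    --seed 7 --outdir fx
canary run --alignment fx/alignment.fasta --interest fx/interest.txt \
    --seed 7 --outdir out
```

which prints

```
classified 2 sequences of interest: canary=1, potentially_problematic=1
```

and writes `out/verdicts.tsv`:

```
id    label                    checking_isomorphic_to_base  comp_p  placement_matches_full  canary_checking_isomorphic
CNRY  canary                   true                         0.82    false                   n/a
LBAX  potentially_problematic  true                         0.01    n/a                     false
```

Read: `CNRY` leaves the base relationships intact (isomorphism holds), is
compositionally unremarkable (p = 0.82), but sits in different positions
in its checking tree and the full tree — a canary. `LBAX` fails the
composition test (p = 0.01), and adding it to the canary dataset moves
the canary (canary-checking tree not isomorphic) — potentially
problematic, excluded from the minimal dataset. Comparing the full and
minimal trees shows how much the one excluded sequence distorted:

```
$ canary compare out/full.nwk out/minimal.nwk
shared leaves: 11
rf_distance: 8
isomorphic: False
```

All outputs (trees per role, minimal alignment, JSON summary, config
echo) land in `out/`; re-running the same configuration reproduces them
byte for byte.

Other subcommands: `canary simulate` runs the replicated long-branch
attraction experiment (or scores pre-existing replicate alignments via
`--replicates-dir`), `canary comptest` runs the compositional screen
standalone, and `canary fixtures` generates the `clean`, `canary_lba`,
`saturated` and `no_canary` scenarios. `configs/` contains documented
replication configurations for the published 18S case studies, the
simulation study and the opsin screen; the underlying alignments are
external data and must be supplied by the user.

## Documentation

`docs/methods.md` describes the statistical model, the formalization
choices (placement, isomorphism, the parametric-bootstrap composition
test), the fixture constructions and their rationale, numerical
tolerances, and known limitations.
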