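# Methods

This note documents the statistical machinery behind `canaryseq`: the
models, the formalizations chosen where the verbal description of the
canary approach leaves room, the numerical settings, what the synthetic
data do and do not emulate, and the limitations a user should know about.

## Tree comparisons

All verdict logic is topological and unrooted. Rooted Newick input is
unrooted on parse (a degree-2 root is suppressed, branch lengths summed);
support values and internal labels are tolerated and dropped;
multifurcations are supported.

* **Isomorphism** (checking vs. base tree, canary-checking vs. canary
  tree) is defined as Robinson–Foulds distance zero on the shared leaf
  set after pruning the focal sequence: the strictest defensible reading,
  since RF = 0 exactly when the nontrivial split sets coincide.
* **Position** of a leaf is its *placement*: the unordered collection of
  leaf-label sets of the subtrees attached at the leaf's attachment node.
  Two trees place a focal leaf identically when, after restriction to
  their shared leaf set, these collections are equal. This is the most
  local, testable formalization of "found in the same position"; it is
  insensitive to rearrangements far from the focal leaf.
* Placement is compared between the checking tree and the full tree. The
  base-tree placement is recoverable from the recorded trees for
  diagnostics but plays no role in classification.
* Branch lengths never influence any isomorphism or placement decision.

The canonical Newick writer orders children everywhere by their smallest
descendant label and starts from the internal node adjacent to the
overall smallest leaf label, so byte-identical output certifies identical
topology; branch lengths are emitted with full round-trip precision.

## Substitution models and likelihood

Nucleotide models: JC69 and GTR; protein models: Poisson and LG (the LG
exchangeabilities and frequencies are embedded as published constants).
All rate matrices are scaled to one expected substitution per site per
unit branch length. Among-site rate variation uses the discrete-gamma
approximation with equal-probability categories (default 4) whose rates
are conditional means on the quantile bins, normalized to mean one; a
gamma shape of `None` disables rate variation.

The likelihood engine is Felsenstein pruning over compressed site
patterns, with gaps and IUPAC ambiguity codes marginalized (an all-gap
sequence contributes a constant factor — a property the two-taxon
closed-form tests exploit by padding a star tree with an all-gap third
leaf). Likelihoods are computed from directional edge "messages" (the
conditional likelihood of the data on one side of an edge), rescaled per
pattern against underflow. The two-pass message computation makes the
full-tree likelihood available at any edge and reduces single-branch
optimization to one small matrix product per function evaluation.

Branch lengths are optimized by per-branch bounded Brent iteration
(bounds 1e-9 to 10 substitutions/site, `xatol` 1e-5) in sweeps; within a
sweep only the messages across the branch just changed are refreshed, and
the exact likelihood is re-evaluated at sweep boundaries, keeping the
best exact assignment seen — the returned likelihood therefore never
falls below the input. Default stopping: improvement < 1e-3 log units or
5 sweeps (the pipeline uses these defaults throughout).

Tree search is neighbor joining on corrected distances (JC69 for
nucleotides, −ln(1−p) for proteins; saturated pairs replaced by a
configurable ceiling, default 5.0 substitutions/site, with a logged
warning) followed by hill-climbing NNI. On trees of ≤ 8 leaves every NNI
candidate is fully re-optimized; on larger trees candidates are screened
by re-optimizing the five branches around the rearranged edge and the
accepted candidate is then fully re-optimized. All ties — NJ joins and
NNI candidates within 1e-9 log units — break by canonical label order,
making inference a pure function of (alignment, configuration): the
pipeline's verdicts are reproducible byte for byte.

GTR parameters, when not supplied, are fitted on the NJ topology:
frequencies from pooled empirical counts (plus 0.5 pseudocount),
exchangeabilities by L-BFGS-B in log space with GT fixed at 1, branch
lengths re-optimized before and after; the fitted model is then held
fixed during NNI. External engines (PhyML, PhyloBayes wrappers, …) plug
in through a command template with `{alignment_phylip}` and
`{out_newick}` placeholders; the contract is "write one Newick tree,
exit 0", with captured stdout/stderr attached to any failure.

## The compositional homogeneity screen

The screen is a parametric bootstrap at the plug-in estimate — the
frequentist analogue of the posterior-predictive composition checks used
in Bayesian practice, chosen because the package deliberately contains no
MCMC machinery. For the alignment under test (the checking dataset, under
its checking tree — a documented choice, switchable by configuration),
`n_sims` alignments (default 99) are simulated on the fitted tree and
model. The statistic is the per-sequence L1 deviation from the pooled
composition, Σ_s |f_seq(s) − f_pooled(s)| — bounded by 2, interpretable,
and insensitive to length differences. The Monte-Carlo p-value is
(1 + #{null ≥ observed}) / (1 + n_sims); a sequence is heterogeneous when
p < α (default 0.05, per sequence, no multiplicity correction — the
screen is applied one sequence of interest at a time).

Two properties matter in practice:

* **Missing-data masks are replicated in the null.** Each simulated
  sequence is masked at exactly the observed sequence's gap/ambiguity
  positions before computing compositions. Without this, a sequence with
  many missing sites compares a high-variance observed deviation against
  low-variance full-length nulls and is spuriously flagged.
* **The test is slightly conservative by discreteness.** With
  n_sims = 99 the p-values lie on the grid k/100 and rejection requires
  p < α, so the exact null rejection rate at α = 0.05 is 0.04. The
  calibration test measures 500 null sequences and checks the rate within
  0.05 ± 0.02 and the p-value distribution within a Kolmogorov band.

## The pipeline

The eight-step classification is implemented exactly as summarized in the
README, with rule order fixed: a sequence whose checking tree perturbs
the base relationships is never composition-tested; a heterogeneous
sequence goes to the noncanary pool irrespective of placement; the
canary/stable decision is placement in checking vs. full tree. The full
and base trees are inferred once and reused (`recompute_full` exists for
callers supplying precomputed trees). If every sequence of interest turns
out to be a canary the noncanary pool is empty and the minimal dataset
equals the canary dataset; the simulation harness separately marks such
replicates "not relevant". Noncanary sequences that were heterogeneous
are processed like any other noncanary sequence in the canary-checking
round, with their heterogeneity recorded in the report, so a user who
prefers to retain all sequences can still interpret every verdict.
Per-interest composition seeds derive deterministically from the
configured seed and the sequence's index, so verdicts do not depend on
which other sequences are tested.

## Simulator and the LBA experiment

Sequences evolve site-i.i.d. on a fixed tree: root states from the
stationary frequencies, per-branch transitions at the site's gamma
category rate; a fixed seed reproduces the alignment exactly.
Terminal-branch elongation multiplies named pendant edges ("increased by
250%" is read as ×2.5 and is a configuration knob; the resulting
pendant-to-next-longest ratio is logged as a diagnostic). The replicated
experiment derives each replicate's seed from the master seed and index,
scores the standard full-data analysis against topological constraints
(clade monophyly with an optional restriction on which taxa the minimal
containing split side may add), and applies the relevance filter:
replicates where the standard analysis is already correct, or where the
pipeline finds no canary or only canaries, are excluded. The success rate
is reported over relevant replicates, alongside per-taxon rejection rates
and a conservativeness probe (how often a failed relevant replicate
excluded a taxon that was not elongated).

## Engineered fixtures

The fixture generator produces alignments whose interest sequences are
built to land in known verdict classes. The generating model throughout
is GTR with skewed frequencies (0.35/0.15/0.15/0.35), transition bias
(AG = CT = 4), and gamma shape 0.5, analyzed under JC69 — the
model-misspecification regime in which attraction artifacts thrive. The
generating tree is two caterpillar clades (pendants 0.08, internals 0.05,
central edge 0.08 substitutions/site).

* `clean`: both interest sequences evolve normally at their true
  positions; expected all-stable, exercising the no-canary branch.
* `canary_lba`: the canary evolves normally at the innermost cherry of
  clade 1, then 85% of its sites are masked to missing — too little
  signal to resolve its position firmly, but its composition is
  untouched. The problematic sequence attaches to clade 2 beside the
  central edge on a ×2 pendant, its composition is biased by an extra
  0.25-substitutions/site segment under GC-swapped frequencies, and 85%
  of the canary's surviving sites are copied into it — the signature of a
  contaminated or partially chimeric fast-evolving sequence. In the full
  alignment it captures the weak canary into a cherry and drags it out of
  its clade; alone, each behaves innocuously. This construction was
  chosen over pure pendant elongation because, under the deterministic
  NJ+NNI engine, elongation alone misplaces the long branch itself but
  does not reliably move the *canary* between the checking and full
  trees — the attraction needs an explicit affinity. The construction
  reproduces the intended mechanism robustly: across seeded fixtures the
  expected verdicts appear in ≥ 90% of runs, the full tree essentially
  never recovers the generating backbone clade, and the minimal tree
  essentially always does.
* `saturated`: two i.i.d. stationary-noise sequences; expected to behave
  as canaries (their placements are signal-free), though two interacting
  noise sequences occasionally demote one another to the noncanary pool —
  tests assert at least one canary plus the partition invariants.
* `no_canary`: both interest sequences evolve at their true positions but
  with GC-swapped composition; the compositional screen routes them to
  the noncanary pool deterministically, the run ends with no canaries,
  and the minimal dataset collapses to the base dataset.

What the synthetic data emulate: substitution-process artifacts
(long-branch attraction, compositional bias, signal erosion) under model
misspecification on a known truth. What they do not: alignment error,
indels and length variation, paralogy and incomplete lineage sorting,
site-heterogeneous composition, and the scale of real gene-family
datasets. Passing the fixture tests demonstrates that the pipeline's
logic and engine behave as designed under controlled artifacts, not that
the approach succeeds on any particular empirical dataset.

## Problem sizes and tolerances

Validation runs use 12-taxon, 1,000-site fixtures (20 seeds for the
recovery study), 500 null sequences for composition calibration, 200
random 6–10-leaf tree pairs for the RF oracle, exhaustive enumeration for
4–5-taxon search checks, and 100,000-site simulations for the
statistical checks (3 Monte-Carlo standard errors). Worked likelihood
values are asserted to 1e-6 against closed forms; branch-length MLEs to
1e-3. These sizes were chosen to exercise every code path at desk scale;
the library itself has no size-dependent switches, and the published
18S/opsin replication configurations (49–98 taxa) run through exactly the
same code.

## Known limitations

* The internal search is NNI-only from an NJ start: adequate at fixture
  scale and fully deterministic, but weaker than SPR/TBR searches on
  large or difficult datasets; the external-engine adapter exists for
  exactly that case.
* The composition screen is a plug-in parametric bootstrap, not a true
  posterior predictive check; it conditions on the fitted tree and model
  and inherits their errors.
* CAT-style mixture models, codon models, indel simulation and
  support-value-aware comparisons are out of scope.
* The pipeline runs once; it is not iterated to convergence. Re-running
  on a minimal dataset is possible but is a user decision.
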