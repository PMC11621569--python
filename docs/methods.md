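# Methods

## Scope and data model

`clocknet` operates on five plain-text inputs: a neuron annotation table
(id, cell type, super class, hemilineage, hemisphere, soma position in µm),
a directed synapse-count table, SWC skeletons (µm), a long-format cluster ×
gene × method expression table (mean scaled expression and fraction of
cells expressing), and a ligand–receptor catalog with EC50 potencies in nM.
Neuron ids are opaque strings throughout: real connectome root ids exceed
53-bit float precision, so id columns are never parsed numerically.  The
internal length unit is the micrometre everywhere because the biologically
meaningful distance thresholds (1 and 14 µm peptide diffusion) are stated
in µm; converting from voxels or nanometres is the reader's job.

## Roster identification

The identification procedure alternates three steps to a fixed point:
expand (morphology-cluster co-members of current roster members become
candidates), filter (soma-distance criterion), close (cell types are
atomic).  The published criterion — a candidate is retained when it lies
"less than twice the average distance away" from a clock cluster — leaves
the reference point open.  We measure the candidate's distance to the
*same-hemisphere cluster soma centroid* and compare it against twice the
cluster's mean pairwise soma distance in that hemisphere, with a strict
`<`.  The centroid is a single robust reference; nearest-member variants
would make acceptance depend on one outlier soma.  Candidates in a
hemisphere with fewer than two assessable cluster members are rejected with
a warning rather than guessed at.  A candidate accepted under two different
clock classes aborts with a conflict error (the original analysis resolved
such cases by manual inspection, which we represent as optional allow/deny
lists, not automation).  The procedure is monotone — the roster never
shrinks — so termination at `max_iter` (default 10) only ever truncates
growth, and the iteration log records whether the fixed point was reached.

## Connectivity

All thresholds are minimum passing counts on per-neuron-pair synapse sums:
significant = 5 ("> 4 synapses"), strong = 10, relaxed = 3, top-partner
shortlist = 80 (inclusive, i.e. "more than 79 synapses per neuron"),
strongest-input focus = 50.  The per-pair threshold is applied *before*
cluster aggregation, so a cluster edge's weight is the sum over
individually significant pairs; the number of surviving pairs and their
mean are reported alongside.  Laterality is taken from the hemisphere
annotations of the pair's endpoints (contralateral iff they differ), never
re-derived from coordinates; pairs with missing labels go to an
`unassigned` bucket so that ipsi + contra + unassigned always equals the
edge total.

Connectivity profiles index each focus neuron by *all* of its input and
output synapse counts over a fixed shared partner index (inputs and outputs
concatenated, unthresholded).  Profile clustering is hierarchical
agglomeration on 1 − cosine similarity; average linkage is the default
because only the similarity, not the linkage, is dictated by the analysis
it reproduces, and it is configurable.  Rows are sorted by neuron id before
linkage so the dendrogram is independent of input order.  Zero profiles are
rejected (cosine similarity is undefined), rather than silently placed.

Disynaptic tracing reports a path source → mid → target iff each hop
passes the per-pair threshold; the middle neuron is unconstrained.  The
implementation is a thresholded table join and is verified against a
brute-force triple loop in the tests.  Path summaries average per-hop
synapse counts *per contributing neuron pair*; the denominator choice is
recorded in the output column names because published per-pathway averages
do not state theirs.

The fan-in estimate is the uniform-convergence arithmetic
(n_upstream / n_downstream) × synapses-per-connection — with one synapse
per connection it counts expected converging partners per downstream
neuron.

## Neurotransmitter consolidation

Only the fast transmitters (ACh, Glu, GABA) are assigned; each neuron
carries at most one (Dale's principle) and hemilineages are expected to be
unanimous.  The rule order is fixed: confidence filter (strictly above
0.62), group fill by cell type, group fill by hemilineage, anatomical
overrides.  The published pipeline lists these steps without an explicit
precedence; we order them from most to least neuron-specific evidence and
keep the order configurable and logged.  Group fill only acts when every
assigned group member agrees — a group containing two transmitters
contributes nothing.  Anatomical overrides (driver-line marker expression)
fill only unknowns; an override disagreeing with a confident EM call is
logged as a conflict and not applied.  Under these rules the unknown count
is non-increasing along the chain and consolidation is idempotent.
Glycinergic co-transmission reported for some ventrolateral neurons does
not fit the single-fast-transmitter representation and is out of the
assignment model.

## Paracrine inference

A cluster expresses a gene (single method) when the fraction of expressing
cells is strictly above 0.49 and the mean scaled expression strictly above
0.208 for peptides or 0.067 for receptors.  Evidence integration requires
two independent positive methods for peptides; receptors alternatively
qualify by a positive live-imaging record alone.  Cluster–cluster distance
is the *minimum skeleton node-to-node distance* over all member neurons —
not soma-to-soma — matching the calibration of the 14 µm default on a
closest-approach measurement of a demonstrated paracrine pair; the
stringent variant (1 µm) demands near-touching arbors.  The KD-tree
implementation is checked against the exhaustive all-pairs loop.  Ligand
potency is a pass/fail filter at EC50 ≤ 500 nM, inclusive ("higher than
500 nM" is what gets disregarded) and never an edge weight, because
published EC50s come from heterologous systems that are not mutually
comparable.  Receptor isoforms with distinct pharmacology are separate
catalog rows.  Edges are directed source(peptide) → target(receptor);
self-edges (autocrine) are allowed and bidirectionality arises only when
both directions qualify independently.  The retention fraction
|edges(1 µm)| / |edges(14 µm)| is defined as 1.0 on an empty loose set (the
degenerate case is logged).

## Synthetic data: what it emulates and what it does not

The generator builds a miniature clock network under fixed study
conditions: nine clusters (one per major clock cell type, 2–5 neurons per
hemisphere), isotropic Gaussian soma clouds (σ = 4 µm) mirrored across the
midline plane, cluster centres 25 µm apart so that neighbouring arbors fall
inside the 14 µm diffusion range while distant clusters do not, branching
random-walk skeletons (30–60 nodes, 2 µm steps) rooted at the soma, the six
reported strong cell-type motifs (including the contralateral DN_1p_A hub),
the lateral-cholinergic / dorsal-glutamatergic transmitter split with a
quarter of each type's predictions degraded below the confidence cut (and
one type left entirely to anatomical overrides), and a peptide complement
anchored on PDF/sNPF with one catalog pair deliberately above the EC50 cut,
one peptide planted in a single method, and one receptor shown only by live
imaging.

Planted synapse counts are Poisson around the motif mean but clipped from
below at the significance threshold: a plain truncated Poisson cannot
guarantee the generator's contract that planted edges always pass, and with
default means (7–14) the clip is rarely active.  Background edges —
between distractors and on clock pairs not covered by any motif — are
uniform on 1..4, strictly below threshold.  Distractor somata sit at four
times the expected mean pairwise soma distance (≈ 2.26 σ for an isotropic
3-D Gaussian) from the nearest cluster centroid, safely outside the 2×
acceptance radius even under small-sample fluctuation of the cluster's
pairwise distances.

Ground truth for paracrine edges is computed by the generator's own
bookkeeping — planted expression × EC50-filtered catalog × brute-force
node-to-node distances at the default thresholds — while the pipeline
recomputes the same edges through its independent code path (per-method
calls, KD-tree distances), so recovery tests compare two routes, not one.

Passing recovery tests therefore show that the pipeline's rules are
implemented exactly, on data whose structure matches the real inputs.  They
do not show robustness to properties the generator omits: proofreading
errors and split/merged neurons, synapse-detection noise near the
threshold, morphology clusters that mix cell types, midline-crossing somata
with ambiguous hemisphere labels, batch effects across expression methods,
or distance inflation from truncated skeletons.

## Numerical choices and degenerate inputs

Duplicate synapse rows are summed at read time; non-positive or non-integer
counts, duplicate expression records, out-of-range fractions and
non-positive EC50s are format errors naming the offending line — there is
no silent coercion.  SWC parents may reference later node ids (resolved
after the full read); a missing root, duplicate ids or disconnected/cyclic
parent links are format errors.  Cosine distances from scipy are clipped at
0 to absorb negative round-off for identical profiles.  Retention, input
share and mean pairwise distance raise on their undefined cases (non-subset
inputs, zero input synapses, fewer than two somata) instead of returning
sentinels.

## Problem sizes

The default synthetic network has 72 neurons (60 clock + 12 distractors),
~2 000–2 500 synapses and ~3 000 skeleton nodes; a full pipeline run takes
about a second.  Oracle-equivalence checks use 100 random 50-neuron graphs
for disynaptic tracing and 100 random skeleton pairs of up to 500 nodes for
the distance computation — sizes at which exhaustive enumeration is exact
and fast, which is the point of an oracle.
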