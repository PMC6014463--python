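# Methods

This note documents the models and rules `icpkit` implements, the
parameters that matter, and the choices made where the published workflow
leaves the details to the analyst at the microscope.

## Probe panels and expected patterns

Panels are modeled as ordered hybridizations of probe targets
`(chromosome, arm, locus class, color)`. The Standard Resolution layout
(23 hybridizations; pter=green, cen=yellow, qter=red; no p-arm probe on
acrocentrics; aqua Yp; X and Y share one hybridization) and the
five-color Acrocentric mix are built in; arbitrary panels round-trip
through a JSON schema.

A karyotype is expanded into *physical chromosome units*: normal copies,
terminal-deleted copies, reciprocal-translocation derivatives (each
carrying the partner's displaced terminal), unbalanced derivatives, and
Robertsonian derivatives (two pericentromeric loci constrained to be
fused, two long-arm terminals). `expected_pattern` projects the units
through a hybridization's targets to obtain the noise-free per-cell signal
pattern — the ground truth for simulation and the oracle for recovery
tests.

## Karyotype grammar

One grammar serves simulator input and published result strings:
`count,sex[,events...]` with optional `icp.` prefix and `[cpN]` suffix,
`"XX or XY"` sex alternatives, mosaic clones joined by `/`, and event
tokens `+N`, `-N`, `del(N)(band)`, `t(A;B)(band;band)`,
`der(B)t(A;B)(band;band)`, `der(A;B)(q10;q10)`. Band text inside
parentheses (including `?`) is carried verbatim and never interpreted;
class-level comparisons ignore it. A `+N` following a Robertsonian over
chromosome N is folded into the event (`extra_copy_of`), and a declared
count that tallies a Robertsonian derivative as two chromosomes is
tolerated and canonicalized (the translocation trisomy has 46
chromosomes). A bare `t(a;b)` between two acrocentrics is read as a
centromeric (Robertsonian) fusion.

## Nucleus model

The nucleus is the unit disk — a microscopy projection; three-dimensional
modeling adds nothing to the rule logic. Each chromosome unit is an
*oriented territory*: a uniformly placed center with a uniformly random
axis, whose loci sit at ordered axial positions (pter at one end, the
pericentromere in the middle, qter at the other end) plus isotropic
Gaussian jitter. An early isotropic-cluster variant was rejected: with all
loci drawn from one Gaussian blob, distinct signals of one chromosome are
frequently closer than the fusion radius, so no noise-free configuration
reliably separates them, and the model provides no notion of a terminal
signal sitting "away from" its centromere. The oriented segment gives
both: separated signals in the normal state, and a well-defined displaced
terminal (one far from every pericentromeric anchor of its chromosome)
when a translocation moves a subtelomeric target onto another derivative.

Parameters (lengths in nucleus-radius units):

| parameter | default | meaning |
| --- | --- | --- |
| `n_cells` | 20 | cells per hybridization, the scoring minimum |
| `arm_span` | 0.20 | axial distance pter–cen and cen–qter |
| `territory_sd` | 0.03 | Gaussian jitter around each locus position |
| `fusion_distance` | 0.10 | true-fusion placement bound; default extraction radius |
| `min_separation` | 0.15 | minimum distance between non-fused true signals |
| `p_detect` | 1.0 | probability a true signal yields a spot |
| `p_split` | 0.0 | probability of a duplicate spot (placed within `fusion_distance/4`, so it re-merges at extraction) |
| `background_rate` | 0.0 | Poisson mean of spurious spots per color per cell |

Robertsonian fused groups are co-placed within `fusion_distance`.
Non-fused true signals are rejection-sampled (up to 200 layouts per unit)
to stay more than `min_separation` apart — the analyst's practice of
scoring only well-spread nuclei. Under the defaults this is also the
regime in which extraction recovers the expected pattern exactly in every
cell, which the test suite asserts for a panel of representative
karyotypes and, end to end, for all 41 clinical-table karyotypes.

Chance colocalization is studied by disabling the separation constraint
or by setting `territory_sd = inf`, which makes every locus position
i.i.d. uniform in the disk; in that mode the per-cell juxtaposition rate
is validated against an independent vectorized Monte-Carlo estimate of
P(min cross-color pair distance < r) and is monotone in both the fusion
radius and the number of spots.

All randomness flows from one integer seed; per-hybridization substreams
are derived from the CRC-32 of the hybridization id, so outputs do not
depend on iteration order and identical inputs give byte-identical spot
tables.

What the simulator does **not** emulate: optics and point-spread
functions, intensity variation (a "dim" signal is modeled as absent),
satellite association of acrocentric p-arms (chance juxtaposition stands
in for it), nuclear sub-compartments, and slide-to-slide hybridization
efficiency differences. Passing tests therefore show that the calling
rules are implemented and internally consistent — not that real POC
material would score identically.

## Extraction

Spots of one cell are clustered by single linkage: connected components
of the graph joining spots at distance ≤ the fusion radius (closed ball,
so exact-coordinate ties merge deterministically). Same-color spots in a
component count as one signal — this is what re-absorbs split signals — 
and a component with two or more colors is one juxtaposition event. The
radius defaults to the simulator's `fusion_distance` and is a
configuration knob, because the physical distance scorers use at the
microscope is not standardized. Clustering is verified against a
brute-force all-pairs connected-components oracle.

## Calling rules

* **Copy number**: modal per-cell cluster count per color; ties break
  toward the diploid expectation of 2, then the smaller count (fewest
  false aberrations).
* **Mosaicism**: a secondary population needs ≥4 cells *and* ≥20% of
  cells. The published rule is stated at n=20 exactly ("four of 20");
  requiring both is the conservative extension to other n.
* **Juxtaposition**: abnormal iff the fraction of nuclei with the
  two-color fusion strictly exceeds 20% — 4/20 is normal, 5/20 abnormal.
  `estimate_cutoff` lets a laboratory set its own threshold as the larger
  of the worst observed control fraction and the one-sided Clopper–Pearson
  upper bound on the pooled control rate.
* **Displacement**: a terminal cluster is displaced in a cell when no
  pericentromeric cluster of the same chromosome lies within
  `displacement_radius` (0.30); a chromosome-level displacement call needs
  more than `displacement_cutoff` (0.40) of informative cells. These two
  numbers are this package's quantification of a signature the source
  workflow judges visually. Under the default geometry a truly displaced
  terminal is unanchored in ≈85% of cells (it re-attaches only when its
  territory lands near an anchor by chance) while an attached terminal at
  axial distance 0.20 with jitter 0.03 is mis-scored in ≈1% of cells, so
  0.40 sits far from both distributions; the 20% fusion cut-off is *not*
  reused because the displacement null is geometric, not a juxtaposition
  rate.
* **Breakpoint refinement** (ordered-band panels): the break lies between
  the last present and first absent band of the terminal absent run.

## Genome assembly

Baseline copy number = modal pericentromeric count across autosomes
(2 → diploid, 3 → triploid, 4 → tetraploid); per-chromosome gains and
losses are re-expressed against it. Sex: Y copies from the aqua Yp count;
X copies from the shared pericentromeric count minus Y (robust to terminal
X deletions; the green Xp count is cross-checked and a deficit becomes
`del(X)(p?)`). Robertsonian events come from abnormal pairwise fusions on
the acrocentric mix — unbalanced when exactly one participant exceeds
baseline, in which case the corresponding whole-chromosome gain is
consumed by the derivative so the same evidence is never reported twice.
Terminal losses pair with displaced extra terminals into
`der(B)t(A;B)(?;?)`; displaced-but-balanced chromosomes pair among
themselves into balanced translocations. Pairing is fewest-event with
ascending-chromosome tie-breaking (the published workflow resolves such
pairings by expert judgment, which must be mechanized here); ambiguity and
unpaired evidence are flagged states, never errors.

Mosaic composition, in order of precedence: a whole-genome ploidy mosaic
(the same two copy numbers on at least half the autosomes, including
"flipped" hybridizations where the minority class reached a local
majority); populations differing in sex complement (maternal cell
contamination is *not* computationally distinguished from true
mosaicism — both are reported as populations with a flag); and one- or
two-chromosome mosaics. Rendering lists the abnormal clone first and
appends `[cpN]` with N the smallest cell count over hybridizations.

## Problem sizes and numerical choices

The validation round trips run at the study's own scale: 20 cells per
hybridization, 24 hybridizations per case, one case per printed karyotype
(41 clinical specimens; 31 distinct classes for the larger laboratory).
Statistical calibration tests use 100,000 Monte-Carlo replicates against
2,000–2,500 simulated cells and 3-standard-error bands; the noise
regression (95% detection, 0.1 background spots per color) uses 100
seeded replicates. Rejection sampling falls back to the last drawn layout
after 200 attempts (never reached under defaults); spot coordinates are
float64 throughout and clustering uses exact distances, so noise-free
results are reproducible bit for bit given a seed.

## Known limitations

* Detection dropout masquerades as mosaicism at the 4-of-20 boundary: at
  `p_detect = 0.95` roughly 10% of cells lose one signal, so spurious
  low-fraction secondary populations appear in a substantial minority of
  noisy replicates. Real scorers discount single-signal losses; the
  implemented rule follows the published threshold literally.
* Cells are not matched across hybridizations (each hybridization is its
  own slide), so assigning aberrations to populations in multi-clone cases
  is heuristic, guided by fraction agreement.
* Interstitial deletions, inversions, microdeletions/duplications and
  marker chromosomes are out of scope, as they are for the
  subtelomere+pericentromere probe design itself.
* The high-resolution banded panel is supported only generically (ordered
  band presence → breakpoint interval), not as a concrete color map.
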