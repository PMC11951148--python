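# Methods

## Problem setting

Given (i) a protein database (e.g. translated transcriptome
assemblies), (ii) a set of characterised reference enzymes labelled
with their product category, and (iii) optionally profile HMMs for the
family's domains, the pipeline recovers the family's members, groups
them into putatively isofunctional clusters, and ranks the members
most distant from every reference as candidates for functional
novelty. All stages are deterministic; randomness exists only in the
synthetic-data generator.

## Pairwise alignment and the alignment score

Pairwise comparison is optimal Smith–Waterman local alignment with
affine gaps (no heuristic seeding or banding). The default scoring is
BLOSUM62 with gap costs `open + k·extend` = 11 + k, matching the
common `blastp` parameterisation; `X` scores 0 against everything, so
ambiguity-derived unknowns neither reward nor punish an alignment.
Custom matrices in NCBI text format are validated at load (symmetry;
negative expected score under Robinson–Robinson background
frequencies).

Significance uses Karlin–Altschul statistics
`E = κ·m·n·e^(−λS)` with the standard gapped BLOSUM62/11/1 constants
(λ = 0.267, κ = 0.041) and — deliberately — the **per-pair** search
space `m·n` rather than a database-wide length. This makes E-values
symmetric in the two sequences, independent of database size, and
reproducible across runs; the cost is that the SSN alignment score
AS = −log₁₀E lives on its own scale, offset from scores produced by
database-wide BLAST services. Thresholds must therefore be tuned on
the data at hand (the `tune` module exists for exactly this), and the
operating points quoted for other pipelines do not transfer
numerically. Finite-size (edge-effect) corrections and gapped-λ
refitting are omitted: they shift all AS values smoothly, and
threshold tuning absorbs the calibration error.

AS is computed in log space from the raw score, so an E-value that
underflows double precision still yields a finite score, and is
clamped below at 0. Percent identity is counted over the aligned
columns (matches, mismatches, gaps) of one optimal traceback; to keep
it symmetric under argument swap, the pair is ordered canonically (by
residue string) before traceback, making tie-breaking
order-independent.

## Harvest

Three searches can be combined; the candidate pool is their **union**
by default (a sequence genuinely belonging to the family can fail any
single detector; intersection is available as a config option):

* *similarity*: a database sequence hits if its best local-alignment
  E-value against any bait is at or below the cutoff.
* *profile similarity*: PSI-style iteration. Per bait, the current
  hits are projected onto bait coordinates via their pairwise
  alignments; column probabilities are observed counts mixed with
  BLOSUM62-implied pseudocounts (weight 0.5 per observed count),
  converted to log-odds scores divided by λ so the same
  Karlin–Altschul machinery applies approximately; the database is
  rescreened against this position-specific matrix with the same
  affine-gap local alignment (a vectorised kernel; the within-row gap
  recursion is an exact prefix-maximum because re-opening a gap is
  never cheaper than extending an open one). The hit set is unioned
  with the previous round, so it grows monotonically in iterations
  (default 1 extra round).
* *domain*: per-HMM presence calls (below); a sequence counts as a
  domain hit if any supplied HMM detects it. Per-HMM accounting of
  hits lacking individual domains is reported.

After the union, the length filter removes hits shorter than
`min_length` (default 700 residues; the boundary is inclusive — a
700-residue hit is retained). The run report prints the bait length
range so the user can justify the filter against the reference
family's length distribution. A Venn summary counts hits per
strategy combination; the cells partition the union.

## Profile HMMs

The `phmm` module implements a plan7-style profile HMM (match,
insert, delete states; the seven core transition types) scored by the
forward algorithm in **single-hit local** mode with a deliberately
simple, fully proper path model: entry picks a (start position, match
state) pair uniformly (probability `1/(M·L)`); every match state exits
with probability `1/(M+1)`, its three core transitions scaled by the
complement; flanking residues are emitted by the background null and
contribute nothing. Because entry and exit are proper distributions,
total path mass is a sub-probability and a sequence emitted at
background frequencies can never score above 0 bits — a useful sanity
invariant that a "free endpoints" formulation violates. Scores are
log-odds in bits; `X` emits at background in every state (log-odds 0).

Models come from two sources: a HMMER3 ASCII subset reader (NAME,
LENG, ALPH, COMPO as background, per-state emissions/transitions,
`STATS LOCAL FORWARD` as Gumbel calibration — files written by
`hmmbuild` parse directly), and `build_hmm`, which estimates a model
from an MSA: columns with ≤50% gaps become match states, emissions are
counts mixed with `w·background` (default w = 0.5; as w → ∞ the model
degenerates to the null), transitions are Laplace-smoothed counts of
the implied state paths, and the background is the MSA's own residue
frequency (floored so no residue has probability zero). `star_msa`
builds an adequate detection MSA from unaligned references by
projecting each onto an anchor via pairwise alignment; insertions
relative to the anchor are dropped, which is acceptable for detection
but not for per-column analysis.

Domain presence uses either a bit-score cutoff, or — for calibrated
models — a Gumbel-tail E-value with effective search-space size 1
(per-sequence), so cutoffs are independent of database size.
Tightening either cutoff can only remove domains, never add them.

This is not HMMER parity: no multihit or glocal modes, no posterior
decoding, no envelope definition, no entry/exit priors. For
presence/absence at a threshold — the only downstream use — the
single-hit local score suffices, and its simplicity is what allows
exact verification against brute-force path enumeration in the tests.

## SSN construction

All N(N−1)/2 pairs of retained sequences are aligned once into an
edge table keeping every pair with AS > 0 (one expensive pass; each
threshold build afterwards is cheap — required by the sweep). Every
sequence is a node: no representative-sequence collapsing, because
singleton counting at full resolution is the point of the analysis.
The network at a threshold keeps edges with AS ≥ t; clusters are
connected components; components of size 1 are singletons. Cluster
summaries report size, label composition, purity (modal-label
fraction among labelled members; absent when a cluster has no
references), per-clade composition, and the fraction of all nodes and
of reference nodes falling in the k largest clusters. Percent
identity is carried on edges for reporting but never used for
thresholding (single-threshold design).

## Threshold tuning

The qualitative criterion — clusters should separate different
products without splitting isofunctional groups by phylogeny — is
formalised over the labelled reference nodes as constrained
optimisation:

* **functional mixing** M(t): fraction of different-label reference
  pairs co-clustered at threshold t. This is computed at *component*
  level on purpose: two families can merge through unlabelled
  intermediate nodes without any direct cross-label reference edge,
  and a cluster containing two products is exactly the failure being
  guarded against. The edge-level variant (fraction of surviving
  reference–reference edges joining different labels) is reported as
  a diagnostic column, NaN when no reference edge survives.
* **same-label cohesion** C(t): fraction of same-label reference
  pairs co-clustered; nonincreasing in t.
* **phylogenetic fragmentation** F(t): fraction of labels whose
  references are split over more than one component; reported but not
  optimised, since C already penalises splitting (optimising both
  would double-count).

`select_threshold` returns, among thresholds with M(t) at or below
the mixing tolerance (default 0), the one with maximal C(t), ties to
the smaller threshold (less fragmentation). Because C is
nonincreasing, with tolerance 0 this is the smallest threshold whose
clusters mix no labels. The mixing/cohesion formalisation is this
package's construction — a reproducible, testable stand-in for expert
judgement of cluster maps — and is labelled as such.

## Novelty candidates

Singletons that are themselves references are dropped from the report
but counted in a summary line (n singletons = r reference + (n−r)
uncharacterised). The novelty score is the maximum percent identity
to any reference — chosen because "no reference closer than x%
identity" is the natural statement of evidence for novelty — ranked
ascending, ties by id; the best alignment score to a reference is
emitted as an extra column, not used for ranking. An optional clade
allowlist restricts the report (e.g. to angiosperms). Conserved-motif
screening finds, per motif, the candidate window with fewest
mismatches to the consensus (ties leftmost) and reports substitutions
positionally (`C5Y` = consensus residue C at motif position 5 observed
as Y); windows exceeding the mismatch budget report "motif not
found". The default catalogue contains only the OSC MWCYCR motif;
users supply their own for other families. Clade statistics
(sequences, species, sequences-per-species; computed for the full set
and the singleton subset) expose lineage overrepresentation
descriptively — no statistical correction is applied, mirroring how
such skews are handled by manual clade focus.

## Synthetic data generator

`synth.generate` emulates the statistical structure the pipeline
assumes, with full ground truth:

* A root ancestor is drawn from Robinson–Robinson background
  frequencies; per-family ancestors descend from it; members descend
  independently from their family ancestor (star topology within
  families). Modelling the families as subfamilies of one superfamily
  is essential: threshold tuning is only meaningful when
  between-family similarity is real, as it is for a homologous enzyme
  family.
* Substitutions follow the conditional model implied by BLOSUM62
  (replacement drawn from P(b|a), identity excluded at the event
  level but reachable by back-substitution), so diverged sequences
  keep realistic residue preferences. Realized identities are
  therefore validated against the generator's own Monte-Carlo
  expectation (`expected_pairwise_identity`), not `1 − rate`.
* Indels: per-site events (default 0.01) of geometric length
  (mean 2), insertions drawn from background.
* Fragments: contiguous truncations of randomly chosen members,
  bounded below the length filter (default ≤ 650 of a 750-residue
  scale).
* Novel singletons: heavily diverged direct descendants of the root
  (default substitution rate 0.6), related to every family only
  distantly — harvestable, but unlinked at a sensible threshold.

Defaults (seed mandatory; 5 families × 8 members, ancestor length
750, within-family rate 0.15, between-family identity target 30%,
2 references per family, 4 fragments, 3 novel singletons) were chosen
to mirror a realistic enzyme-family mining scenario — full-length
multi-domain enzymes ~750 residues, within-family identity ~70–75%,
between-family ~30–40%, novel singletons ~20–30% to the nearest
reference — and produce measured alignment-score bands of roughly
264–306 (within family), ≤ ~100 (between families) and ~25–40
(singleton to anything) under the default scoring. `plant_as_gap`
verifies by sampling that the within band clears every cross-class
band by a margin (default 5 AS units, so a threshold can sit strictly
inside a usable gap — very short ancestors fail this feasibility
check); if not, it lowers the within-family rate and raises singleton
divergence and re-verifies.

What the generator does **not** emulate: tree-structured evolution
within families (star topology only), domain-architecture variation,
alignment-twilight compositional biases, assembly chimerism, or
isoform redundancy. Passing end-to-end tests therefore demonstrates
the pipeline's internal correctness and its behaviour under the
assumed band structure, not performance on the messiness of real
transcriptome data.

Synthetic end-to-end runs (tests and the acceptance script) use a
similarity cutoff of 1e-20 and, at shorter simulated lengths, 1e-10:
per-pair E-values are offset from database-wide BLAST E-values, and
these values keep planted singletons harvestable while excluding
noise — the analogue of choosing an operating point inside the stable
range of a cutoff sweep. The HMM bit-score cutoff in those runs is 25
bits (overwhelming odds, conservative for detection).

## Numerical choices

* Gap convention `open + k·extend` everywhere (Biopython's aligner is
  configured with `open_gap_score = −(open+extend)` to match).
* The within-column delete-state chain in the HMM forward/Viterbi
  recursion is vectorised with `logaddexp.accumulate` /
  `maximum.accumulate` after factoring out the cumulative D→D weight;
  structurally-impossible `−inf` transitions are clamped to −1e9
  inside the cumulative sum only (they never lie on a valid path) to
  avoid NaN poisoning.
* E-value logs use `log10(m·n)` as a single term so the value is
  bit-identical under argument swap.
* Backgrounds and emission mixtures are floored (1e-9 relative) so a
  residue absent from a small MSA cannot produce −∞ log-odds.
* Components are sorted by (size desc, smallest member id), rows of
  every table lexicographically; all outputs are byte-stable across
  reruns.

## Problem sizes

The test suite and acceptance script run the full pipeline at
5 families × 8 members × 750 residues (≈50 sequences, ≈1,000
all-vs-all alignments, ~1–2 minutes total) and the oracle suites at
500 alignment pairs, 200 HMM cases and 200 random graphs — sizes
chosen so exhaustive enumeration oracles remain exact and the whole
suite runs comfortably on one CPU. The pipeline itself scales
quadratically in retained sequences (the all-vs-all pass dominates);
mining collections beyond ~10⁴ sequences would want a heuristic
prefilter in front of `compute_edges`, which is out of scope here.

## Known limitations

* λ and κ are fixed configuration values, not refitted per matrix;
  AS offsets are absorbed by threshold tuning, as discussed.
* The profile HMM is a detection model, not a HMMER replacement.
* `star_msa` discards insertions relative to the anchor.
* Clustering is connected components only; no community detection.
* The PSI-profile E-value reuses the pairwise λ, which is an
  approximation; profile hits are therefore unioned with (never
  substituted for) plain similarity hits.
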