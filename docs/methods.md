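# Methods

This note records the models, conventions and numerical choices behind
`movemine`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the bundled synthetic data
can and cannot demonstrate.

## Discretization

Each 0.1 s GPS sample is banded on three channels:

| Channel | Bands (closed/open bounds as implemented) |
|---|---|
| velocity (m/s) | Walk [0, 1.70) · Jog [1.70, 3.90] · Run (3.90, 5.00) · Sprint [5.00, ∞) |
| acceleration (m/s²) | Deceleration (−∞, −0.20] · Neutral (−0.20, 0.20) · Acceleration [0.20, ∞) |
| turning angle (deg) | Straight [0, 10) · Acute [10, 45) · Large [45, 90) · Backwards [90, 180] |

The 4 × 3 × 4 = 48 triples map bijectively onto `a`–`z`, `A`–`V` in
velocity-major, acceleration-middle, turning-minor order — the unique
simple enumeration consistent with every attested character assignment
(`e` = Walk·Neutral·Straight, `u` = Jog·Acceleration·Straight,
`S` = Sprint·Acceleration·Straight, …). Note the mixed inclusivity of
the Jog/Run boundary: 3.90 m/s is Jog, not Run.

**Channel provenance.** The device acceleration and turning-angle
channels are preferred when present. Otherwise acceleration is the
central finite difference of velocity at 10 Hz (one-sided at the trace
ends; zero for a single fix), and turning angle is the absolute
difference of consecutive great-circle initial bearings folded into
[0°, 180°]. Conventions for degenerate geometry: the first and last fix
of a trace get angle 0 (no three-fix corner exists); steps shorter than
a motion epsilon (default 0.01 m) define no heading, so the last moving
heading is carried forward, and a trace that never moved contributes
angle 0. These choices avoid undefined bearings without inventing
motion.

**Inactive periods.** A maximal run with velocity < `v_min`
(default 0.2 m/s) lasting ≥ `t_min` (default 2.0 s) is deleted, and the
remaining maximal runs become the discrete sequences of the
player-match corpus. Both parameters are configurable; the defaults are
stand-ins for the upstream convention, which is not fully specified in
the literature the thresholds come from. Sub-threshold runs shorter
than `t_min` are deliberately left in place.

## Pattern mining

**Support semantics.** Support is sequence-level everywhere: the
fraction of sequences in one player-match corpus containing at least
one occurrence of the pattern (contiguous for substrings, subsequence
containment for LCS patterns, item containment for itemsets).
Occurrence-weighted support was considered and rejected as the default
because presence/absence is what the downstream feature matrix
consumes. Threshold comparisons use `count ≥ minsup·n − 1e-9` so exact
fractions are not lost to floating point.

**Closed contiguous mining** is level-wise: positions whose
k-substring is frequent are the only candidates for (k+1)-substrings
(anti-monotonicity). Closure drops any pattern with a frequent
one-character extension of equal support count; since support is
monotone under extension, equal-support chains make this equivalent to
closure against super-patterns of any length. Patterns at the length
cap cannot be extended and are therefore closed when frequent. A
brute-force enumerator (all substrings, pairwise closure) is retained
as an oracle, guarded to ≤ 10⁴ total symbols.

**LCS stage.** The pairwise LCS is the standard quadratic DP; the
backtrack is made deterministic by always taking a character match and
otherwise moving in the first argument on ties. Sequences are clustered
by normalized Levenshtein distance (edlib; distance divided by the
longer length) with complete-linkage agglomerative clustering into
min(25, n) clusters, and each cluster is folded through the pairwise
LCS in descending-length-then-lexicographic order. Distance, linkage,
cluster count and fold order are not fixed by the source framework and
are exposed as configuration; the defaults are recorded here as this
package's convention. Empty folds are dropped; the >20-item filter is
applied downstream, as for itemsets.

**Closed itemset mining** enumerates closed sets directly by
prefix-preserving closure extension (LCM-style): each closed set is
produced exactly once as the closure of a tidset, so runtime scales
with the number of closed sets rather than the full frequent lattice —
essential because long movement sequences make almost every small
character set frequent. A powerset-enumeration oracle (alphabet ≤ 20)
provides the independent check.

**Unions.** Pattern identity is (kind, items); a contiguous "ab" never
equals the itemset {a, b}. The per-algorithm unique union keeps, for
every pattern, the list of corpora it was extracted from with the
per-corpus support; the length of that list (extraction frequency) is
the ranking used for most/least-frequent-50 overlap analysis, with ties
broken lexicographically.

## Comparison and classification

Jaccard similarity is |X∩Y|/|X∪Y| on pattern identities and is
undefined (an error) when both sets are empty. Printed scores are
rounded half-up to the reported precision. Position partitions are
plain set arithmetic, so |A only| = |A| − |shared| holds exactly.

The feature matrix has one row per player-match, one column per union
pattern, entries 1 when the pattern is a member of that observation's
*mined* set (not merely of its raw symbol stream — the dataset is
derived from extracted patterns). Cross-validation is shuffled,
unstratified 10-fold (shuffle seed 10). The five classifiers use
library defaults except: random forest seed 1, logistic regression with
L1 penalty (liblinear), MLP with 300 iterations and seed 5. Precision,
recall and F1 are averaged over the two classes weighted by class
support by default (macro averaging is available); the single-number
reporting convention does not name a positive class, so per-fold values
are class-aggregated. Importance for the linear model is the absolute
coefficient — the only non-negative transform consistent with reporting
all-positive scores for a signed L1 model — ranked descending with
lexicographic tie-break, truncated to 20.

## Synthetic cohorts

The generator emulates a two-position cohort (hooker vs winger)
directly in movement-unit space. Each position has a 48-state Markov
chain built from three factors: velocity-band persistence 0.97 per
0.1 s sample (10 Hz kinematics are strongly autocorrelated; this also
produces the run-like patterns — `eeee…`, `uuv`, `GGG` — that dominate
real mined sets), an acceleration band conditioned on the velocity-band
change, and an independent turning distribution (0.70 / 0.22 / 0.06 /
0.02). Motifs are planted as atomic blocks at a configured rate per 100
symbols (default 2): hookers `uuv` and `mn`, wingers `ji` and `SS`;
the null cohort gives both positions one identical archetype.

Symbols are emitted back to GPS channels by drawing uniformly inside
each band's interval (open ends shrunk by 10⁻³; Sprint capped at 9 m/s,
|acceleration| at 4 m/s²; active Walk velocities floored at 0.3 m/s so
only generated gaps cross the inactive threshold). In angle mode the
turning angle is a device channel and discretization is an exact round
trip by construction; in coordinate mode positions are synthesized on a
local flat grid so consecutive bearings realize the drawn angles within
1° at interior fixes. Inactive gaps (velocity < 0.15 m/s, uniform
2.5–6 s) separate active bursts of uniform 4–12 s, so the splitter is
exercised rather than bypassed; the generator records the true active
segments as ground truth.

**Cohort scale.** The default study conditions are 10 players per
position × 5 matches = 100 player-match observations of 600 s each —
about one tenth of a full-season elite dataset, sized so that each
corpus holds ~50 discrete sequences (the 5 % support threshold then
requires a pattern in ≥ 3 sequences) and the feature-to-observation
ratio stays comparable to the real studies. This matters for the null
calibration: with very few observations and thousands of binary noise
features, cross-validated accuracy on an uninformative cohort has far
more than binomial variance, and no classifier can sit reliably inside
a 99 % binomial band around the prior. At the default scale all five
classifiers do, while a cohort with disjoint planted motifs is
separated at accuracy 1.0.

**What passing does not show.** The generator draws independent values
within bands (no within-band autocorrelation), plants motifs with no
tactical context, uses one archetype per position (no player
idiosyncrasy, fatigue, or opposition effects) and flat-earth geometry
over a few hundred metres. Tests passing on it validate the symbolic
pipeline — banding, splitting, mining, set arithmetic, the
classification harness — not any claim about real rugby league
movement; the published real-data magnitudes (unique-set sizes in the
thousands, 91 % MLP accuracy) depend on private GPS data and are not
reproduced here, only the arithmetic identities among their printed
counts.

## Known limitations

* The LCS stage's clustering granularity bounds the number of patterns
  per corpus by the cluster count; with mostly-singleton clusters the
  surviving (≤ 20-item) pattern set is small, and LCS classification
  accuracy is accordingly near chance on synthetic cohorts — consistent
  with it being the weakest of the three pattern types.
* Sequence-level support makes no distinction between a pattern
  occurring once or many times within a sequence.
* No GPS quality control (HDOP, dropout, smoothing) is attempted;
  inputs are assumed clean and on a strict 0.1 s grid.
* `heading_change` uses spherical bearings but no projection-grade
  geodesy; sub-centimetre steps are treated as stationary.
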