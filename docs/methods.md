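# Methods

## Scope and model

`acetomod` implements a comparative-genomics survey of the gene modules
that enable acetoclastic methanogenesis in the class *Methanosarcinia*,
plus the growth-curve kinetics used to phenotype engineered strains.

Acetate catabolism needs two things: an **acetate-activation** module —
either the two-enzyme acetate kinase + phosphotransacetylase pair
(Ack+Pta, one ATP per acetate, typical of *Methanosarcina*) or the
one-enzyme AMP-forming acetyl-CoA synthetase (Acs, two ATP equivalents,
typical of *Methanothrix*) — and a membrane **energy-conservation** module
that re-oxidizes the reduced ferredoxin produced by acetyl-CoA
dismutation: the Na+-translocating Rnf complex, the H+-translocating
energy-converting hydrogenase Ech, or the F420:methanophenazine
oxidoreductase lacking its F420-interacting head subunit FpoF (written
Fpo′; Fpo′ plus FpoF is the full Fpo complex). Genomes are classified by
which combination they carry:

| category | activation | energy conservation |
|---|---|---|
| I | Acs | Fpo′ only (no FpoF, no Rnf, no Ech) |
| II | Ack+Pta | Rnf or Ech |
| III | Acs | Rnf |
| IV (hypothetical) | Ack+Pta | Fpo′ only (no Rnf, no Ech) |

Rules are evaluated in the order III, II, I, IV; anything else is
unclassified. III precedes I because III is defined by the Acs/Rnf
co-occurrence and most such genomes also carry full Fpo. The Rnf/Ech
exclusions in I and IV make the four rules pairwise disjoint except on
profiles carrying *both* activation modules — a combination never
observed in sequenced genomes and surfaced separately by the
co-occurrence report rather than blocking classification. A 64-profile
audit over all boolean module combinations verifies that rule order is
irrelevant outside that dual-activation cell.

## Homology search

Detection is profile-HMM based. `hmmio` parses HMMER3 text profiles
(`HMMER3/f` and `HMMER3/b`; other dialects rejected), converting the
negative-natural-log body to probabilities and capturing GA/TC/NC
bit-score cutoffs and STATS LOCAL Gumbel calibration when present. Parsed
models must satisfy normalization invariants (emission rows and per-state
transition fan-outs sum to 1 within 1e-4) or parsing fails loudly.

Two engines score proteins:

* **internal** (default) — a single-hit local Viterbi scorer: uniform
  1/M entry into any match node, free exit from any match node, delete
  states silent, i.i.d. background null taken from the model (flanking
  residues cancel). Scores are bits; the ambiguous residue X scores as
  background (log-odds 0). The dynamic program is verified against a
  brute-force path enumerator on tiny models, exhaustively and on seeded
  random instances. E-values use the Gumbel tail
  `E = n_targets * (1 - exp(-exp(-lambda (S - mu))))` with the model's
  VITERBI mu/lambda; models without STATS get `E = +inf` with a warning,
  leaving score cutoffs in charge. `n_targets` is fixed at search start
  to the number of proteins searched. This scorer is deliberately
  simpler than HMMER (no MSV/Forward filters, no multihit model, no
  composition correction).
* **hmmsearch** — a subprocess wrapper over a HMMER `hmmsearch` binary
  for bit-for-bit fidelity on real models; its `--tblout` is parsed by
  `hmmio`.

Filtering follows the survey protocol: keep a hit when its full-sequence
E-value is strictly below 1e-3 AND its bit score reaches the model's
noise cutoff (NC). Both filters apply jointly; the comparison can be
relaxed to `<=` and the cutoff key switched (NC/GA/TC/none). When a model
lacks the requested cutoff the fallback chain NC → GA → TC → E-value-only
is walked with a logged warning at each step. The sequence-level cutoff
is compared against the full-sequence score (HMMER's default reporting
surface); domain-level cutoffs are out of scope.

## Module calling

A module is present when hits cover at least a threshold number of
**distinct** member models: ≥4 of six Rnf subunits, ≥4 of six Ech
subunits, ≥5 of seven Fpo′ subunits; Ack, Pta, Acs and FpoF each require
their single model. Ack+Pta is a conjunction (both enzymes); a genome
with only one gets a partial-module warning. One protein passing two
member models of the same complex counts toward both distinct subunits
(complex subunits are homologous; the ambiguity is warned about, never
silently dropped). Member model names are configuration (YAML), so real
accession sets can replace the built-in placeholder names. No
genome-completeness gating is applied by default.

Prevalence summaries report k/n per taxon at any GTDB rank, keeping the
exact rational fraction and a nearest-integer percent for presentation.
Tree overlays prune a reference Newick tree to the surveyed genomes
(GTDB `RS_`/`GB_` accession prefixes stripped for matching; unmatched
leaves reported, not fatal; branch lengths summed through collapsed
unary nodes) and emit one iTOL DATASET_BINARY text file per module flag
plus a leaf-to-category TSV — plain-text, diff-able formats.

## Growth kinetics

Doubling times come from linear regression of log10(OD600) on time over
an automatically selected exponential window; `T_D = log10(2)/slope`.
Lag time is where the regression line meets the t = 0 log10-OD:
`T_Lag = (log10(OD(0)) - intercept)/slope`. A culture whose OD never
rises 0.05 above its start over an observed span of at least 4,320 h
(six months) is called no-growth; a flat curve observed for less than
that span is indeterminate, never no-growth. Strain comparisons use the
two-sided unequal-variance (Welch) t-test with Welch–Satterthwaite
degrees of freedom, implemented explicitly and cross-checked against an
independent reference implementation in the tests.

**Window selection.** The published analyses chose exponential windows
manually; a reproducible pipeline needs a deterministic rule. A window
qualifies when it has ≥ `min_window` (default 4) points, positive slope,
R² ≥ `r2_min` (default 0.95), **and every contiguous sub-window of
`min_window` points also clears the same bar**. The longest qualifying
window wins; ties go to the steepest slope, then the earliest start. The
local-R² condition is the load-bearing refinement: a long window's
aggregate R² forgives a few off-trend points, so without it the longest
window creeps one to three points into the lag or stationary phase and
biases the slope; with it, noise-free lag+exponential curves are
recovered exactly (machine precision) and noisy curves still select the
full exponential stretch. Degenerate inputs (too few points, flat or
non-positive-slope series) return `indeterminate`. OD values must be
positive — blank subtraction happens upstream — and times strictly
increasing.

Two boundary behaviours are worth knowing. When the stationary ceiling
falls between sample points, the first, mildly capped point can pass the
local-R² bar and drag the slope by well under a percent; exactness
claims therefore hold for spans that end before the ceiling (or align it
with the sampling grid). And a gently *linear* OD rise clears R² ≥ 0.95
on its late log-window — no R² threshold can reject it — so linear
growth fits near the threshold rather than being flagged; telling linear
from exponential growth remains the analyst's call, as it was in the
original study (such cultures were reported as not determined).

## Synthetic data

The generator builds every fixture with explicit seeds and serialized
ground truth; identical seeds give byte-identical files.

* **Profiles** (`make_hmm`): match emissions put 0.9 on the consensus
  letter (rest uniform); inserts and the background are uniform;
  transitions favour match-to-match (0.9). Cutoffs are constructed to
  make threshold logic sharp: NC is the midpoint between the minimum of
  50 emission-sampled positive scores and the maximum of 50
  shuffled-consensus decoy scores, TC the minimum positive, GA their
  midpoint — so noise-free planted genes always clear NC and
  composition-preserving decoys never do. Gumbel VITERBI parameters are
  moment-matched to 200 decoy scores (lambda = pi/(sd sqrt 6),
  mu = mean − gamma/lambda); the MSV and FORWARD slots repeat the
  Viterbi fit because HMMER requires all three STATS lines.
* **Communities** (`make_community`): each genome carries mutated copies
  (default per-residue substitution probability 0.05, no indels) of the
  genes its category pattern requires — pattern I: Acs + seven Fpo′
  subunits; II-rnf: Ack, Pta, six Rnf subunits plus full Fpo (as in most
  natural category-II genomes); II-ech: Ack, Pta, six Ech subunits; III:
  Acs, six Rnf subunits, full Fpo; IV: Ack, Pta, seven Fpo′ subunits;
  unclassified: decoys only — plus 10 decoys per genome, each a residue
  shuffle of a planted gene (the hardest null under an i.i.d. scoring
  model). Subunit genes are 120 residues: short enough for fast exact
  scoring, long enough that positive and decoy score distributions are
  separated by hundreds of bits. Genus labels group the patterns and the
  tree groups the genera (seeded random caterpillars). The default
  community is two genomes per pattern (12 total); the co-occurrence
  emptiness property is checked on a 12-genome community drawn only from
  the patterns observed in nature (no IV, no dual activation).
* **Growth curves** (`make_growth_curve`): OD stays at `od0` through the
  lag, doubles every `t_d` hours afterwards, saturates at `od_max`, and
  is multiplied by lognormal noise `exp(noise_sd * N(0,1))` (the noisy
  study condition uses noise_sd = 0.02, about 2% CV).

What the generator does **not** emulate: indels and phylogenetically
correlated sequence evolution, paralogy and operon structure, genome
incompleteness, plate-reader artefacts, or biased amino-acid
composition. Passing tests therefore demonstrate the correctness of the
pipeline's logic under its stated model, not the sensitivity/specificity
of any particular real HMM set on real proteomes — for real surveys the
hmmsearch engine and curated models with their own NC annotations carry
that burden.

## Problem sizes and numerics

Default study conditions: 12-genome communities, 23 profile HMMs of
length 120, 10 decoys per genome (~5.3k scored pairs per survey); 200
noisy growth replicates at sigma = 0.02; 1,000 Welch null draws. The
Viterbi kernel is numba-jitted (pure-Python fallback) and all log-space
arithmetic is done directly in bits. Probability round trips through
HMMER3 text are exact to 1e-6 (7 decimals of -ln p); zero probabilities
are written as `*`. The E-value tail uses `expm1` so small-E values keep
full relative precision. Percentage formatting rounds half to even via
Python's `round`, with the exact fraction retained alongside.

The headline fractions printed in the source survey (over 133 GTDB
r214.0 *Methanosarcinia* genomes) require the pinned external inputs —
GTDB genomes, Prokka annotation, the published HMM accession set — and
hours of CPU; they are reproducible through the same pipeline with the
hmmsearch engine but are outside the hermetic test surface. One known
discrepancy in that source: category II is printed once with denominator
134 while the survey size is 133; this package always uses the surveyed
genome count as denominator.
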