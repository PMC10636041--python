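# Methods note

This note records the statistical model behind `plexquant`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made in the implementation.

## Generative model

A panel of `T` targets is assayed in wells `w` of a plate. Each target `t`
has a four-parameter logistic (Hill-shaped) response in expected reporter
counts:

```
mu[t, w] = e_w * ( D_t + h_t * A_t * sum_a K_{t,a} * x_a^{B_t} / (x_a^{B_t} + C_t^{B_t}) )
```

- `x_a` — molar concentration of antigen `a` in the well.
- `D_t` — zero-concentration count floor (background binding), counts.
- `A_t` — amplitude of the concentration-dependent signal, counts.
- `C_t` — half-maximal concentration, molar.
- `B_t` — Hill slope, dimensionless.
- `h_t ∈ (0, 1]` — "hot" antibody fraction. Mixing DNA-conjugated (hot)
  with unconjugated (cold) detection antibody attenuates signal linearly
  in the hot fraction, which is how high-abundance targets are kept on
  scale in one multiplexed reaction. The generator attenuates the most
  abundant ~15% of targets with `h` drawn from (0.02, 0.5).
- `K_{t,a} ∈ [0, 1]` — relative cross-affinity of assay `t` for antigen
  `a` (self = 1, default 0 otherwise). Nonzero off-target entries create
  cross-reactive signal for the QC module to detect.
- `e_w > 0` — per-well efficiency (pipetting, ligation, amplification),
  drawn log-normally (σ = 0.15). The spiked-in internal control (mCherry)
  has expectation `e_w * ic_mean` in every well, so dividing by it cancels
  `e_w` exactly in expectation — this is the invariant the IC
  normalization step exploits.

Observed counts are negative-binomial around `mu` with size parameter
`nb_dispersion` (variance `mu + mu²/size`; `inf` degenerates to Poisson).
The default size of 100 puts a ~10% floor on the per-measurement CV,
matching the intra-plate precision a well-behaved plate shows; a much
smaller size would make the 30% CV quantitation criterion unattainable at
any sequencing depth, which is a property of the instrument model, not of
the analysis.

Each count unit emits `reads_per_count` reads (integer, default 1) laid
out as `[SMI][spacer][TMI_capture][TMI_detection][spacer]` with a 10-base
sample barcode, 12-base target barcodes and 4-base fixed spacers. Reads
are corrupted by iid per-base substitutions and indels, and with
probability `chimera_rate` a read carries the detection TMI of a different
target (antigen-independent ligation / PCR chimera). Barcode books are
rejection-sampled to a pairwise edit-distance floor (default 5), which is
what makes two-error tolerance unambiguous.

All randomness flows from a single seeded `numpy.random.Generator`; a
given seed reproduces panels, counts and reads bit-for-bit.

## Demultiplexing

For each read, the SMI, capture TMI and detection TMI fields are matched
independently against their barcode books. A field matches a reference
when its edit profile — indel count minimized first, then substitutions —
satisfies: at most two substitutions with no indel, or one indel with at
most one substitution. Minimizing indels first pins the indel count to
the length difference of the aligned strings, which gives an exact,
enumerable definition of the profile used by the test oracles. Among
accepted candidates the lexicographically smallest (indels, substitutions)
profile wins; a tie makes the field ambiguous. Reads whose two TMI fields
resolve to different targets are tallied per well as chimeric; reads with
an unresolvable SMI are tallied without a well. Every input read lands in
exactly one of assigned / unassigned / ambiguous / chimeric, so read
counts are conserved.

Implementation: a banded edlib alignment (k = 2) prefilters candidates;
the exact profile is then computed by a small weighted Needleman–Wunsch
with indel cost 1024, making (indels, substitutions) lexicographic
minimization a single scalar minimization. Per-field results are
memoized, which makes throughput ~10⁶ reads/s in pure Python because real
reads repeat a small set of observed barcodes.

## Normalization

1. **IC**: `(counts + 1) / (IC_counts + 1)` per well; the +1 keeps
   zero-count cells finite. The internal-control row is consumed.
2. **IPC → NPQ**: `NPQ = log2(ic / median_IPC(target) × 10⁴)`. Dedicated
   inter-plate-control wells (a pooled sample run on every plate) anchor
   each target's scale across plates; the 10⁴ rescale keeps typical NPQ
   values positive (a well at the IPC median sits at log2(10⁴) ≈ 13.3).
3. **Intensity normalization** (alternative to 2): rescale each plate's
   per-target median onto the global per-target median. Idempotent, and
   after one application every plate median equals the global median to
   floating-point precision.
4. **Cq bridge**: single-plex qPCR readouts map to the linear signal scale
   as `2^(37 − Cq)`, i.e. one cycle = one doubling, referenced to cycle 37.

## Calibration

Standard curves are fitted on IC-normalized signals from 12-level,
3-replicate dilution series (10-fold steps) plus ≥3 blank wells. The 4PL
`y = D + (A − D)/(1 + (x/C)^B)` is fitted by `scipy.optimize.least_squares`
with residuals weighted by `1/y` (observed signal), i.e. 1/y² weighting of
squared error, which balances the decades-wide span of signals. Fits are
multi-started over slope guesses B ∈ {0.5, 1, 2}; asymptote starts come
from the extreme mean signals, `C` starts at the geometric
mid-concentration, and `C` and `B` are optimized on a log scale, which
enforces positivity without explicit bounds. Backfitting inverts
the 4PL analytically; signals at or beyond the asymptotes raise rather
than extrapolate.

- **LOD**: the larger of backfit(mean(blanks) + k·sd) and
  backfit(A + k·sd), with k = 3 for multiplexed (NGS) assays and k = 2.5
  for single-plex (qPCR) assays; sd is the sample standard deviation
  (n − 1). Degenerate blanks (sd = 0) leave the LOD undetermined and
  flagged rather than silently zero.
- **LLOQ/ULOQ**: the widest contiguous window of dilution levels such
  that every level has CV < 30%, both endpoints backfit-recover within
  70–130%, and at most one interior level violates recovery. Ties in
  log10 width resolve to the lower LLOQ. The search is an exhaustive
  O(levels²) enumeration — small, exact, and matched against an
  independent enumeration oracle in the tests.
- Panel summaries report per-target `log10(ULOQ/LLOQ)` and the cumulative
  dynamic range `log10(max ULOQ / min LLOQ)` across targets.

## QC

- **Precision**: per-target CV of linear-scale values across replicate
  groups, averaging group CVs; values below the target's LOD are excluded
  (and counted), a group entirely below LOD reports NaN. Log2-scale SDs
  convert to geometric CV as `100·sqrt(exp((sd·ln2)²) − 1)`.
- **Detectability**: fraction of sample wells strictly above the
  plate-specific LOD; a target is detectable when this exceeds 50%.
  Panel-level detectable counts get exact Clopper–Pearson binomial
  confidence intervals via `scipy.stats.beta.ppf`.
- **Cross-reactivity**: with pooled-antigen screens, score =
  `(max nontarget-pool signal − bg) / (mean target-pool signal − bg) × 100`
  where `bg` is the median nontarget-pool signal; an assay whose target
  pools do not rise above background is flagged failed rather than scored.

## Pooling design

198 targets are partitioned twice into 45 pools of 4–5 so that no
unordered pair of targets shares a pool in both partitions; three
homolog pools are appended (93 pools total, 20 pM per antigen). Every
target then appears in exactly two pools whose intersection is that
target alone, so a cross-reacting protein is identified by intersecting
its two elevated pools. Set 2 is constructed by randomized swap repair:
swaps between pools are accepted when they do not increase the violation
count, until no set-1 pair recurs. Pigeonhole feasibility requires the
pool count to be at least the largest pool size; infeasible requests
(e.g. 8 targets in 2 pools) fail fast with that explanation. A planted
cross-reactant is only recoverable when it lies outside the assay's own
two pools — inside them it is masked by the assay's expected self-signal.

## What the generator does and does not emulate

Emulated: logistic dose–response with floors and saturation, hot/cold
attenuation, well-efficiency variation and its internal-control remedy,
count overdispersion, barcode read errors and chimeras, dilution-series
plates, IPC anchor wells, cross-reactive off-target binding.

Not emulated: binding kinetics and incubation-time effects, washing and
matrix interference, PCR amplification bias beyond a per-well scalar,
optical duplicates and UMI collapse, carryover between wells, plate-edge
effects, sample-level biology (disease groups, longitudinal structure).
Problem sizes used in tests and examples (8–200 targets, 24–96 wells,
scaled-down read depth) are this package's own choices for desk-scale
validation; the algorithms are size-independent.

## Numerical choices

- Indel cost 1024 in the profile DP turns lexicographic (indels, subs)
  minimization into one integer minimization (any barcode is far shorter
  than 1024).
- 4PL fitting optimizes `log C` and `log B` and retains the weighted-RSS
  winner of the multi-start.
- Blank/LOD statistics use ddof = 1 throughout.
- Clopper–Pearson bounds come from `scipy.stats.beta.ppf` with the usual
  closed-form endpoints at x = 0 and x = n.
- The intensity-normalization idempotency and IC efficiency-cancellation
  invariants are asserted to 1e−12 relative tolerance in the tests.

## Limitations

- The +1 offset in IC normalization biases very low counts; the exact
  efficiency cancellation holds for expectations, not for the offset
  estimator at small counts.
- The quantifiable-range rule needs ≥2 passing levels to produce a
  nonzero-width range; heavily attenuated (small `h`) targets at low read
  depth may report undetermined limits, which is surfaced via flags.
- The swap-repair pool search is randomized; it is validated on every
  run but is not a constructive existence proof for arbitrary sizes.
- Demux throughput relies on memoization, which assumes reads repeat
  observed barcode fields; adversarial all-distinct fields degrade to the
  per-read alignment cost.
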