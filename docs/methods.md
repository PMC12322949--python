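# Methods

`kinseq` models recognizer-based single-molecule protein sequencing: peptides
immobilized one-per-nanoaperture are degraded residue by residue by
aminopeptidases while fluorophore-labeled N-terminal amino-acid (NAA)
recognizers bind the exposed terminus reversibly. Each recognized residue
yields a *recognition segment* (RS) — a train of fluorescence pulses whose
duration distribution is characteristic of the (recognizer, NAA) pair — and
the ordered series of RSs, with per-RS pulse-duration (PD) statistics, forms
a peptide's *kinetic signature*. The package implements the full
computational chain: in-silico peptide screening, kinetic simulation,
primary analysis (dye calling, segmentation), alignment with target-decoy
FDR, and the discrimination statistics.

## Kinetic model

Residues are processed N→C. For the exposed residue with cognate recognizer
*r* and mean pulse duration μ(r, aa):

- With probability `binding_prob` (default 0.9 per cognate pair) the residue
  produces an RS at all; otherwise it is silent, like a dark residue.
- During each unbound interval, binding (rate 1/`mean_interpulse`) races
  aminopeptidase cleavage (rate 1/`cleavage_mean_time`). The number of
  pulses in an RS is therefore geometric with mean
  `cleavage_mean_time / mean_interpulse` (~120 at the defaults), and
  unbound gaps are exponential with scale `ip·cl/(ip+cl)`.
- Pulse durations are exponential with mean μ — the memoryless law for a
  single-molecule bound state. The cleavage clock runs only while the
  recognizer is unbound (a bound recognizer shields the terminus); cleavage
  therefore never truncates a pulse. Both choices are modeling conventions;
  the duration law is the standard single-exponential dwell-time model.
- Dark residues (no cognate recognizer) contribute a silent exponential
  cleavage gap. A per-residue dropout probability (default 0.01) subsumes
  photobleaching and peptide loss; the run ends at `run_duration`
  (default 36,000 s, a 10 h run).

Pulse intensity and lifetime are Gaussian around the dye's configured
photophysics. The shipped dye table places the six dyes on a grid separated
by ≥6 SD on both axes, so dye calling is easy at defaults and the mixture
model is exercised rather than stressed; raising the SDs turns dye confusion
into a real error mode.

PTMs act multiplicatively: a modifier scales the residue's binding
probability (`binding_prob_factor`) and/or mean PD (`pd_factor`).
Phosphotyrosine defaults to binding factor 0.1 and PD factor 1.0 — the PTM
readout of interest is *fewer* Tyr recognition events, not a changed PD.
Both factors are free parameters, not measured values.

## Calibration table

The default table is a reconstruction: cognate sets LIV={L,I,V},
YFW={Y,F,W}, AS={A,S}, NQ={N,Q}, E={E}, R={R} (12 of the 20 canonical
residues, matching every recognizer named in kit documentation); an
alternate table adds a combined D/E recognizer. Mean PDs anchor on the
printed kinetic values — PD(L)=0.35 s and PD(I)=0.23 s for the LIV
recognizer, a 5× N/S ratio (N=1.0 s vs S=0.2 s) and a 9× L/V ratio
(V=0.35/9 s) — with all unprinted entries set to 0.2 s. PD depends only on
(recognizer, residue, PTM); positional context effects are not modeled,
although real signatures show them. All of this is user-overridable through
the JSON or three-file TSV table format.

## Primary analysis

Dye calling fits one full-covariance Gaussian per table dye on
(intensity, lifetime), means initialized at the configured dye photophysics
(no label switching), tolerance 1e-6, ≤500 iterations, fitted on a ≤50,000
pulse subsample and applied to every pulse. Components whose fitted weight
is <1e-3 are treated as empty: with a fixed component count, dyes absent
from a run leave their component free to collapse onto stray points, and
such components must not claim pulses. A populated component far from every
configured dye raises an error rather than silently mis-identifying dyes.

Segmentation merges consecutive pulses while the dye call is unchanged and
the inter-pulse gap stays below `gap_threshold`; segments with <3 pulses are
discarded (an RS is a pulsing region, not a lone pulse). The default
threshold is 12× `mean_interpulse`: within-segment gaps are exponential, so
the chance a gap exceeds k× its mean is ≈e^(−k), and a read carries on the
order of 10³ gaps — a 5× threshold would fragment nearly every read, while
12× keeps spurious splits below ~1% of reads and still splits at every dark
residue (silent gaps ~Exp(120 s) ≫ 12 s). A consequence worth knowing:
*successive residues sharing a recognizer merge into one RS* (their
boundary gap is ~2 s on average), so positions inside same-recognizer runs
are represented collectively by one segment; the per-position outputs then
populate those positions only through binding-failure combinatorics. This
mirrors a stated limitation of the real analysis chain (successive identical
residues are hard to resolve).

Per-RS summaries carry both mean and median PD; alignment consumes the mean,
reporting favors the median.

## Alignment and FDR

A read (ordered RS list) is aligned to a reference profile (ordered non-dark
steps with expected PDs) by global dynamic programming over monotone
pairings. An aligned pair scores `match_bonus` (+2) when recognizers agree,
minus `pd_weight·|ln(observed mean PD / expected PD)|` — a scale-free,
symmetric kinetic agreement term (the functional form is this package's
choice) — or `mismatch_penalty` (−3) otherwise; internal/leading gaps cost
−1 per skipped reference step or unmatched read RS, and trailing gaps on
both sides are free (reads truncate; segmentation can fragment tails). The
DP is verified against an exhaustive enumeration oracle on all small
instances.

Decoys are internal shuffles of each target (C-terminal residue anchored, as
the library chemistry conjugates through the terminal Lys; PTMs travel with
their residue), resampled until the decoy's expected RS sequence differs
from every target's **and** the decoy preserves the target's count of
mergeable same-recognizer adjacencies. The second constraint matters:
segmentation fuses same-recognizer runs, and the printed targets alternate
recognizers perfectly, so an unconstrained shuffle presents systematically
fewer segments than a target and its score null stops mimicking false
target matches. The pipeline pools five decoy draws per target and the
q-value computation normalizes by the decoy/target profile ratio
(q(s) = D(s)/(r·max(1, T(s))), monotonized): with a single decoy per target
the empirical null has so little tail resolution that in a substantial
fraction of runs a target-like null peptide escapes it entirely, and
realized FDP at q ≤ 0.1 exceeded its nominal level until the pooled null
was adopted. Calibration is tested over 20 seeded mixed runs of targets
plus shuffle-distributed background peptides.

Each read is assigned to its best-scoring profile; ties break toward a
target, then lexicographically.

## Discrimination statistics

Aligned RSs are routed back to reference positions through the DP traceback;
each aperture contributes at most one value (its RS mean PD) per position,
and positions aligned in zero reads are absent rather than zero-filled —
dark positions can therefore never appear. The PD fold change between two
peptides at a position is the geometric mean of per-flow-cell ratios of
across-aperture mean PDs; this makes fold(a,b)·fold(b,a)=1 hold exactly and
pairs with a two-tailed one-sample t-test of log ratios against 0 (flow
cells are the replicate unit, n=3 by default; type-I error of this test is
verified at ≈5% under a null simulation). Zero-variance or single-replicate
inputs are flagged degenerate with an undefined p-value. Per-position tests
are reported without multiplicity correction (a Holm helper exists but is
off by default).

The PTM readout is the percentage of apertures containing ≥1 RS of a given
recognizer; the default denominator is apertures with any RS (switchable to
all loaded apertures), and conditions are compared per recognizer with a
Welch two-sample t-test across flow cells.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis chain relies on:
exponential PDs with (recognizer, NAA)-specific means, geometric pulse
counts per RS, dark-residue silent gaps, dye photophysics with Gaussian
noise, aperture loading and dropout, and independent flow-cell replicates.
It does not emulate raw camera traces (pulses arrive pre-extracted),
positional context effects on kinetics, recognizer depletion or
multi-molecule apertures, or instrument-specific noise; passing tests
therefore validate the analysis logic and its statistical calibration under
the stated kinetic model, not performance on real instrument data. Because
reads are assigned before estimation, each peptide's retained PD
distribution is slightly truncated away from its sibling's — position-4
estimates in the Leu/Ile experiment run ~2% above/below their true means,
visible in the recovery outputs and inherent to assign-then-estimate.

## Problem sizes and determinism

Bench-scale analyses use three flow cells × 2,000 apertures per condition
with loading probability 0.3 (~1,800 reads per pair experiment), which
puts the position-4 standard error near 0.1% and makes the headline
quantities stable to well within their tolerances; unit tests use smaller
runs sized to the property under test. All randomness flows from one master
seed via `numpy.random.SeedSequence` spawning; identical configs and seeds
reproduce results byte-for-byte, and simulated runs carry hidden truth
labels (in a sidecar file the analysis path never reads) so tests can make
exact conditional checks.
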