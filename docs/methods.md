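# Methods

## Target model and ranking

The vault stores four kinds of evidence per protein: gene mapping and
subcellular annotation, six transmembrane-topology predictions,
ordinal IHC levels (`Not detected < Low < Medium < High`, the HPA
vocabulary, compared only through an explicit ordinal map) for a
healthy-tissue panel, and per-cancer patient-level IHC count summaries.

A candidate for a cancer type must have strictly more than 50% of
patients at High-or-Medium (a protein at exactly 0.5 is excluded) and,
by default, pass the transmembrane consensus filter: at least 5 of the
6 predictors call exactly one membrane-spanning segment. Missing
predictor outputs count as disagreement — the quorum stays at 5 — which
is the conservative choice for a screen whose false positives are
expensive. Both the quorum (`min_agree`) and the segment target
(`required_segments`) are exposed, as is a `--no-tm-filter` switch,
because known GPCR-family markers are multi-pass and a user may want
the unfiltered list.

Candidates are sorted lexicographically: healthy High-or-Medium tissue
count ascending, then healthy High count, then healthy Medium count,
then cancer patient fraction descending. The four criteria are ordered
but unweighted; lexicographic order is the only parameter-free reading
of an ordered criterion list, and no weighted-sum alternative is
implemented. Residual ties break on gene symbol purely for
determinism.

Two counting conventions are genuinely defensible for multi-cell-type
tissues; the default collapses each tissue to the maximum level over
its cell types (a tissue with one High compartment is a High tissue —
safety-first for off-target toxicity), so K1 = K2 + K3 holds
identically. `tissue_collapse="per_cell_type"` counts
(tissue, cell type) pairs instead. Proteins with no healthy rows count
zero everywhere but carry `data_gap=true` in the output; absence of
evidence is surfaced, not silently treated as safety.

## Overrepresentation analysis

ORA uses the hypergeometric upper tail including the observed overlap,
P[X ≥ k], equivalent to the one-sided Fisher exact test. The universe
is the user-supplied reference list (for the pipeline: all gene symbols
in the store); query genes outside it are dropped with a logged count.
Sets are restricted to the universe and filtered to sizes in
[5, 2000] by default (both configurable, since reference tools differ
in their defaults). Benjamini–Hochberg FDR is computed per collection,
mirroring how per-database results are usually reported; the
implementation delegates to `statsmodels.multipletests` and is tested
against a longhand step-up oracle. Because the hypergeometric statistic
is discrete, the attainable level at any nominal α is below α; the
test-suite's null-calibration check therefore compares the empirical
false-positive rate to the exactly computed attainable level rather
than to α itself.

## SPR kinetics

The 1:1 Langmuir model is used throughout: association
R(t) = Req + (R_init − Req)·e^(−(ka·C+kd)·t) with
Req = ka·C·Rmax/(ka·C + kd), dissociation R(t) = R0·e^(−kd·t),
KD = kd/ka. Double referencing subtracts the reference flow cell and
then the blank cycle pair, per phase and time point, resampling by
linear interpolation when grids differ (non-overlapping ranges are an
error, not an extrapolation).

Fits are nonlinear least squares (trust-region reflective) in
log-parameter space, which enforces positivity without constraints.
The full kinetic fit shares (ka, kd, Rmax) across a multi-cycle
concentration series and ties each cycle's dissociation amplitude to
the model value at injection end; the off-rate screen fits a global kd
with one free R0 per cycle. Initialization is deterministic: kd from
the log-linear terminal slope of the decay, (Rmax, KD) from a
double-reciprocal regression of end-of-injection response against
concentration, plus a small multiplicative grid of alternative starts;
the lowest final cost wins, ties resolved toward the smaller kd.
Convergence tolerances are 1e-15 on cost and step. Fit windows exclude
the first 2 s after each phase boundary (configurable) to avoid
bulk-shift transients. A single-concentration full fit proceeds with a
warning: ka and kd are then barely separable and the result should be
treated as an off-rate only.

Chi² is the residual mean square SSR/(n − p) (the Biacore convention;
raw SSR available via `normalize=False`). Chi²% is Chi²/Rmax·100 with
values below 5% flagged high-significance. The statistic divides RU²
by RU; it is implemented as defined, not dimensionally corrected. For
dissociation-only fits with no companion full fit, Rmax in Chi²% falls
back to the largest fitted R0 and the output flags the substitution
(`rmax_source="max_R0"`).

## Synthetic data

The generators emulate the *structure* of public annotation sources,
not their payload formats: a proteome table with unique gene symbols,
per-predictor segment counts, a 44-tissue healthy IHC panel with two
cell types per tissue, and 22-patient cancer summaries with optional
intensity/quantity bins. Planted ideal targets are ideal by
construction — ≥5/6 single-TM calls, zero healthy Medium/High tissue,
a guaranteed strict patient majority — so pipeline recovery is checked
against known truth. Decoy levels are multinomial draws from
configurable per-stratum probability vectors; by default 70% of decoys
get multi-pass or disagreeing topology calls and the rest pass the
filter, so ranking is exercised among filter survivors too. The
44-tissue panel size is a fixture choice (HPA-like); only counts reach
the ranking, so tissue names are arbitrary labels.

Sensorgram simulation evaluates the exact 1:1 model per concentration
(association 120 s, dissociation 600 s, 1 s sampling, five two-fold
dilutions from 125 nM by default, run in increasing order) and adds
three artefacts: i.i.d. Gaussian noise per sample, a linear baseline
drift continuing across phases, and a rectangular bulk shift spanning
the association phase. Drift and bulk are identical across the active,
reference and blank traces of a run, so noiseless double referencing
recovers the pure model to machine precision — the basis of the
cancellation and parameter-recovery tests. One blank cycle pair is
generated per concentration series (the minimal double-referencing
requirement). Default kinetic constants (ka = 3.68×10⁵ 1/(M·s),
kd = 4×10⁻⁴ 1/s) sit at the fast-dissociation end of the regime the
screening stage is designed for (off-rates 8×10⁻⁵–4×10⁻⁴ 1/s).

What the generators do **not** emulate: correlated IHC scoring between
tissues or observers, partial/missing annotation coverage,
mass-transport limitation, analyte bivalency, ligand heterogeneity, or
regeneration damage between cycles. Passing tests therefore certify
the computation — filtering, ranking, statistics, referencing and
fitting — on data whose generating model matches the fitted model;
they do not certify robustness to the systematic artefacts of real
public-source snapshots or real chips beyond the simulated
drift/bulk/noise.

## Storage and determinism

The vault is a single-file SQLite database (one file, no services)
with primary keys on the natural row identities, making re-ingestion
idempotent, and indexes on protein, tissue and cancer type. Ingestion
validates every row through the typed records and reports offending
line numbers; child rows referencing unknown proteins fail with the
orphan IDs listed.

Every generator is a pure function of its config (seed included), all
artifacts are written with fixed field order and float `repr`, and the
pipeline embeds a config hash and package version in its run report;
two runs from an identical config are bitwise identical. Per-stage
timings go to the log only, never into artifacts.

## Problem sizes used in the test and acceptance runs

Fixture stores use 15–80 proteins (default 50, 5 planted targets),
44 healthy tissues × 2 cell types, 22 patients; ranking-oracle checks
run 100 random stores; ORA exactness uses universes up to N = 5000 and
1000 random configurations, null calibration 2000 random queries
against 25 sets; kinetic recovery uses five-cycle runs (~3600 fitted
points) with 100 noisy replicates. These sizes give tight binomial and
numerical bounds while keeping the default suite fast on one CPU.
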