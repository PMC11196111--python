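# Methods

## Coordinate system and fragment map

All genomic intervals are 0-based half-open (BED convention). A DpnI cut is
placed at GATC motif start + 2 (`GA^TC`); fragments span consecutive cuts,
so a contig with *n* motifs yields *n* − 1 fragments and regions outside the
first/last cut are excluded (a DamID fragment needs two cuts). The offset
choice only fixes bin boundaries — fragments are counting bins, not
biological objects — and is documented so outputs are bit-stable. GATC is
its own reverse complement, so strand never enters. N bases never match the
motif.

## Differential occupancy model

Reads are assigned to the fragment containing their midpoint (half-open
containment; a midpoint on a cut belongs to the fragment starting there),
which gives every read a unique bin independent of processing order.
Normalisation is log2-CPM with pseudocount 0.5:
`log2((count + 0.5) / library_size × 1e6)`, library size being the sample's
column sum; zero-library samples are excluded with a warning.

The fragment statistic is an empirical-Bayes moderated *t* with *scalar*
variance shrinkage: the pooled per-fragment variance (df = n₁ + n₂ − 2) is
shrunk toward the across-fragment mean variance with prior weight
`prior_df` (default 4), and the *t* statistic gets df + prior_df degrees of
freedom. This is deliberately simpler than a full hierarchical fit: it is
self-contained, and in the `prior_df → 0` limit it reproduces the ordinary
equal-variance *t*-test exactly, which the test suite exploits as an
oracle. The contrast is perturbation − control, so occupancy loss is
negative log2FC; the peak filter takes |log2FC| plus an explicit direction
flag to avoid sign ambiguity.

Peak calling chains fragments with p < 1e-5 while the gap between
consecutive qualifying fragments is ≤ 195 bp, splitting before a fragment
that would push the span beyond 5000 bp. The combined peak p is the Simes
statistic over member p-values (min-p Bonferroni available as an option);
peak log2FC is the mean of member log2FCs (not a refit on merged counts).
BH correction runs across peaks, not fragments, mirroring a peak-level FDR
readout; defaults FDR ≤ 0.05, |log2FC| ≥ 2, direction down. Promoter
annotation uses three 1-kb upstream windows and the priority order
promoter > 5′ UTR > 3′ UTR > exon > intron > downstream(≤ 3 kb) > distal.

## AUCell scoring

Genes are ranked per cell by decreasing expression, ties (notably the zero
block) receiving average ranks — deterministic, unlike randomised
tie-breaking; a seeded random tie mode exists for cross-checks. With
K = ceil(top_frac × G) (top_frac default 0.05), the score is
Σₖ R(k) for k = 1..K over the recovery curve R(k) = #{signature genes with
rank ≤ k}, normalised by the maximum attainable area (all signature genes
at the very top), so scores live in [0, 1] and a brute-force enumeration of
R(k) pins the convention to 1e-12 in the tests. The enrichment threshold is
always explicit (the modelled analysis used 0.196); automatic threshold
selection is not reimplemented. The score is invariant to monotone
transformations of a cell's expression values.

## Context-dependent filter

The four criteria are evaluated independently per gene with a full audit
trail. The loss-of-function gate is made symmetric to the printed
gain-of-function magnitude (log2FC < −1.5, p ≤ 0.05) since only
"significantly decreased" is stated for that contrast. The p column is used
as printed (an `use_adjusted_p` switch reads a q column instead).
"Expressed in receptor-positive cells" is operationalised as ≥ 10% of
receptor-positive cells expressing the gene (threshold exposed and recorded
in the audit); a cluster-co-membership mode is provided as an alternative.
Tightening any threshold can only shrink the candidate set (tested).

## Precursor processing

Cleavage is motif-based: every maximal run of K/R of length ≥ 2 is one site
ending at the run's last residue (KKR is one site, not two); singleton K/R
and furin-style R-x-x-R sites are excluded by default. The signal-peptide
boundary is an input — signal-peptide prediction needs a trained model and
is out of scope. The default of 27 residues follows the printed text for
the modelled precursor; its figure legend marks residues 1–26, a
one-residue discrepancy the caller can resolve by passing 26. Raw
(convertase) products retain the basic motif; maturation iteratively
removes C-terminal K/R (idempotent) and converts a then-exposed C-terminal
glycine into an amide (−0.984016 Da). Monoisotopic masses come from
pyteomics; matching is inclusive at the ppm boundary (default 8 ppm).

pI is found by bisection of the Henderson–Hasselbalch net charge with the
Bjellqvist pKa set (N-term 7.50, K 10.0, R 12.0, H 5.98; C-term 3.55,
D 4.05, E 4.45, C 9.0, Y 10.0), fixed so values are bit-stable; the charge
is strictly decreasing in pH so the root is unique. Net charge is reported
both as the integer heuristic (#K + #R) − (#D + #E) and as the titration
charge at pH 7, since the convention behind a printed "net charge" (H,
termini) is often unstated.

### The synthetic precursor stand-in

`tadakit.synthetic.synthetic_spar_like()` returns a **constructed, not
natural** 445-residue sequence that carries the published composition facts
of the modelled glutamine-rich precursor: a 27-aa signal peptide, 43
glutamines of which 30 sit in six tandem repeats at positions 48–56, 59–62,
64–71, 116–118, 120–122 and 148–150, zero cysteines, integer net charge −6,
pI 5.10, and a dibasic processing cassette
`…KR|SEEASAVPTADKK|FNDMRLKR|DTQLNPADMLALVALVEAGERA|KR…` whose trimmed
products reproduce the mass-spec-confirmed mature peptides. It exists
because the real database record cannot be fetched in an offline build;
tests on it demonstrate that the composition and processing machinery
computes the published quantities correctly for a sequence with exactly
those properties — they are not a re-derivation from the authentic record.
The same applies to the genome constant: the published median GATC fragment
length of the fly assembly (350 bp) needs the assembly itself; here the
generator's geometric spacing law pins the expected median in closed form
(4 + (m − 4)·ln 2 for start-to-start mean m) and the empirical median is
checked against it.

## Activity-monitor analysis

Sleep is ≥ 5 consecutive minutes without beam crossings: on 1-min bins,
membership in a zero run of length ≥ 5; on 5-min bins, any zero bin.
Death is *terminal* immobility strictly longer than 24 h — a mid-series
24-h zero run followed by activity is not death, matching the
record-ending semantics of monitor censoring; a `death_anywhere` flag
implements the stricter reading. All downstream statistics are censored at
the death bin. Anticipation ratios divide activity in the 3 h before a
light transition by activity in the 6 h before it, per day, excluding
0/0 days; recordings are anchored at lights-on (ZT0). Actograms are
day × 288 matrices of 5-min bins (1-min data summed), optionally
double-plotted.

The chi-square periodogram follows the complete-cycle form: for a candidate
period of P bins, K = floor(N/P) cycles (N′ = K·P bins) give column means
M_h and `Qp = K Σ_h (M_h − M̄)² / ((1/N′) Σ (X_i − M̄)²)`, which is
asymptotically χ²_{P−1} under an iid null (verified by Monte-Carlo: the
per-period exceedance at α = 0.05 is ≈ 0.03–0.05). Power is Qp minus the
critical value; both raw Qp and power are returned since some conventions
plot one or the other. Periods are searched 18–30 h in 1-bin steps with
per-period α and *no* multiplicity correction (field convention); the
familywise consequence is characterised, not corrected — on pure Poisson
noise the binary "rhythmic" flag fires for most flies because ~145
correlated periods are each tested at 5%, so the flag is only meaningful
relative to a control group or through the power margin. Flies with best
period strictly above 1440 min are classified long-period.

Known estimator limitation: within a fixed-K regime the used-data length
N′ = K·P grows with the candidate period, tilting the power surface upward
in P by ≈ 3P/(2π²K²) bins at the optimum. For a *pure sinusoid* at 25 h
over 7 days this bias is ~1.3 bins, so single-bin localisation is not
achievable there; waveforms with realistic harmonic content (fly activity
is sharply crepuscular) tighten the peak and bring the bias well under one
bin. This is why the synthetic generator's default waveform is two
von-Mises-type activity peaks per cycle rather than a cosine.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (seed, parameters) and returns a
serialisable `TruthRecord` sufficient to score recovery without
re-simulation. Count data are negative binomial with configurable
dispersion — overdispersion is the regime the moderated statistics must
handle. GATC motifs are placed with geometric start-to-start spacing
(mean 350 bp, the fly-like value); accidental motifs in the random
background are mutated away so the spacing law holds exactly.

The DamID generator's default study condition — 500 tiled 8-kb genes
(≈ 23 fragments each), 350 expected reads per genic fragment, dispersion
150, 30% intergenic background, 3 control + 2 perturbation replicates,
4-fold target depletion — was calibrated once, before freezing, to the
prescribed recovery behaviour (precision/recall ≥ 0.9 at default
thresholds). The regime matters because a planted 4-fold drop measured
against a total-count normalisation lands at
log2FC = −2 + log2(1/(1 − s(1 − ¼))) ≈ −1.96 for a target library share
s ≈ 3%, i.e. slightly *inside* the |log2FC| ≥ 2 gate; recovery therefore
relies on the p < 1e-5 member-selection threshold sitting at or below −2
so that selected fragments clear the gate, and on enough fragments per
gene that every target contributes at least one. Deep coverage emulates
merged technical replicates on active loci.

What the generators do **not** emulate: read-level sequencing error,
duplicate reads, mappability structure, doublets or ambient RNA in the
single-cell matrix, batch effects in the bulk tables, and non-stationary
activity (ageing, entrainment transients) in the monitor series. Passing
recovery tests on this synthetic data therefore demonstrates correctness
of the statistical chain under its stated assumptions, not robustness to
every artefact of real data.

## Numerical choices

Ties in expression ranking: average ranks (deterministic). Simes is capped
implicitly at the maximum member p. BH comes from statsmodels. Degenerate
inputs are defined, not crashed: constant periodogram series give Qp = 0;
0/0 co-expression is 0 with a warning; empty peak sets propagate as empty
tables. The moderated-t denominator guards zero variance (identical groups
give p = 1 at zero effect, p = 0 at nonzero effect). All seeds derive from
a single integer and stay below 2³¹.
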