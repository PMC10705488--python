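# Methods

This note documents the statistical model behind `lohdrive`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions made where the design was open.

## The experimental design being modeled

A hybrid diploid founder, heterozygous at ~40,000 marker sites (~320 bp
mean spacing across a ~12 Mb, 16-chromosome genome), seeds a panel of MA
lines propagated through repeated single-colony bottlenecks for T ≈ 800
generations. Selection is minimized by the bottlenecks, so LOH events and
mutations accumulate nearly neutrally. At the end, each line's end-point
clone is genotyped at the marker sites; an LOH event is visible as a run of
adjacent markers converted to one parental homolog. Three founder types are
compared: a full gene-drive cassette (D), Cas9 without gRNA (C), and an
empty integration cassette (W).

## Simulation model (`simulate`)

Per clone, the number of LOH events is Poisson with mean λ·m·T, where λ is
the per-genome per-generation event rate (default 1.76×10⁻², the center of
published hybrid-yeast estimates), m a per-founder rate multiplier
(default 1), and T the generation count (default 800, the post-hoc estimate
for the design; 750 was the planning value and is available for the power
replication). Each event is terminal with probability 0.192 (the observed
class mix):

- **Terminal (tLOH)**: an arm is chosen with probability proportional to
  its length, a breakpoint uniform along the arm, and the tract runs from
  the breakpoint through the telomere. On arms of a few hundred kb this
  yields median tracts of ~100–200 kb, matching the observed scale.
- **Interstitial (iLOH)**: length drawn log-normal with median 471 bp
  (the observed control-strain median) and shape σ = 1.5 (natural-log
  scale), placed uniformly on a length-weighted chromosome. σ is the one
  shape parameter the data summaries do not pin down; 1.5 spreads lengths
  from tens of bp to tens of kb, the range gene-conversion tracts occupy.

Markers inside an event's interval are set to the chosen homolog (equal
probability per event). Overlapping events are resolved
last-writer-wins in simulation order; the ground truth records both each
event's physical interval and its *surviving marker footprint*, which is
what caller tests compare. SNMs and indels are Poisson with means
rate × ploidy × effective_length × T (defaults 1.67×10⁻¹⁰ and 7.5×10⁻¹²
per bp per generation; the indel literature also contains ~5×10⁻¹² — both
are exposed, the default follows the construct-expectation calculation),
placed uniformly, and never overwrite marker calls.

Marker maps are generated with i.i.d. exponential inter-marker gaps
(mean 320 bp, truncated at 1 bp), i.e. approximately a Poisson process —
only the mean spacing of the real panel is specified, and the exponential
is the maximum-entropy choice. Centromeres sit at a configurable relative
position (default 0.45) and carry no markers, mimicking repeat-masked
pericentromeres; every chromosome therefore has a clean two-arm marker
partition.

Reproducibility: one root seed; per-clone streams are spawned from a
`numpy` `SeedSequence`, so cohorts are bit-identical across runs and
independent of chunking.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level noise and genotyping error (calls are
clean or MISSING), aneuploidy and triploidy, repeat-masked regions other
than centromeres, selection and fitness effects, clustered or
sequence-dependent event placement, and founder-specific marker panels.
Conclusions about caller correctness transfer to real data only to the
extent that upstream genotyping delivers accurate HET/HOM calls.

## LOH calling (`lohcall`)

Coordinates are 1-based, intervals closed; every output header states the
convention. A *tract* is a maximal run of same-homolog homozygous calls;
its boundary is the midpoint between the outermost converted marker and
the adjacent informative marker, or the chromosome end when none exists.
MISSING calls are transparent by default (they neither break a run nor
count as converted); a `break` mode is exposed since upstream pipelines
differ. Tracts of the *same* homolog with boundary gaps strictly below
10 kb merge into one event; a homolog switch between two tracts implies
distinct repair products, so merging never crosses it. Events containing
the telomere-proximal marker of an arm are terminal; an event containing
both arm ends (whole-chromosome homozygosity) is reported terminal and
flagged `possible_aneuploidy`, since coverage-based aneuploidy detection
is out of scope. Breakpoints: midpoint of the event interval for iLOH and
tLOH under 20 kb; 10 kb inside the centromere-proximal boundary for longer
tLOH, reflecting resection extending from the break toward the telomere.

### Correction for undetected events

An event is detectable only if it converts ≥1 marker. With markers
approximately Poisson at mean spacing s, a true length-ℓ event covers a
marker with probability p(ℓ) = 1 − e^(−ℓ/s). The corrected per-clone count
is a Horvitz-Thompson sum of 1/p over detected events, restricted to the
universe of events longer than 17 bp (the shortest detectable scale).
Because boundary extrapolation systematically inflates the observed length
of short events, evaluating p at the observed length under-corrects (~18%
in simulation); interstitial events are therefore weighted by the
model-average detection probability E[p(ℓ) | ℓ ≥ 17 bp] under the
configured log-normal length model, which makes the corrected total
unbiased when the model holds (within ~1% in genome-scale simulations).
Terminal events use their observed length directly (p ≈ 1 there). This is
a deliberate single-formula approximation to the multi-part detection
corrections used with real sequencing data (inter-marker events, events
hidden inside or overlapping terminal tracts); it does not correct for
event-event interactions, which cost a few percent on small toy genomes
but are rare at full genome size.

## Mutation calling (`mutcall`)

Putative variants must already exclude marker sites and ancestral
heterozygosity. Founders without sequence data are imputed at a site when
≥6 descendant end-point clones and *all* other genotyped founders agree on
the call (threshold and unanimity are parameters). Variants observed in
more than one clone are discarded: with per-site hit expectation
μ = rate·T·n_clones ≈ 3×10⁻⁵, the expected number of multiply-hit sites in
the whole experiment is 2L(1 − e^(−μ)(1+μ)) ≈ Lμ² ≈ 10⁻², so recurrent
variants are artifacts, not repeated mutations. Variants within 100 bp of
each other in the same clone are grouped into one complex event by
single-linkage (chains allowed — the observed sets are pairwise-close and
do not disambiguate; single-linkage is the weaker assumption).

## Rates and comparisons (`rate_stats`)

Event rate λ̂ = k/(nT) per genome per generation (k corrected or detected
events, n lines, T generations), divided further by L for per-bp window
rates. The conversion rate is the mean per-clone fraction of the
heterozygous genome converted, divided by T. CIs are percentile bootstrap
over clones. Group comparisons reshuffle founder labels: permutation tests
on the difference of group means (or medians), and a Wasserstein
two-sample test on event positions (statistic ∫|E₁ − E₂|, the 1-d
earth-mover distance; null by label reshuffling, 5,000 Monte-Carlo
iterations by default). Monte-Carlo p-values use the add-one convention
(1 + #extreme)/(1 + N) — never exactly zero — and both tests switch to
exhaustive label enumeration automatically when the split count is small.
Two-sided tests are the default. With integer counts the mean-difference
statistic is lattice-valued; ties make the add-one p conservative
(super-uniform), which preserves validity but means exact-uniformity
checks require continuous data. Chromosome-arm contrasts are Pearson χ²
on founder × arm contingency tables, each strain tested pairwise against
the control with zero-total arms pooled out. Window scans use 50-kb
non-overlapping windows (closed intervals; terminal windows shorter and
length-normalized) with BH correction at FDR 0.05; sliding 10-kb-step
windows are for profiles only. Events are assigned to windows by their
breakpoint — the causal position — rather than by overlap, so one long
event cannot hit many windows.

## Power (`power_analysis`)

Theoretical power: per simulated experiment, a baseline group of n = 95
Poisson(μ = 13.2) counts and an alternate group with mean μ(1 + f_e) are
compared by the two-sided permutation test (1,000 permutations); power is
the fraction of 1,000 experiments with p ≤ 0.01. The closed-form
cross-check is Φ(z − z_{α/2}) + Φ(−z − z_{α/2}) with z = μf_e·√(n)/√(2μ + μf_e).
Note the permutation null pools both groups, so under the alternative its
spread is inflated by the between-group separation (variance
σ² + Δ²/4); at the design point this depresses true power by ~2 points
relative to the unpooled approximation (~83% vs 85%), an inherent property
of the pooled permutation test rather than an implementation artifact.

Observed power: the pooled per-clone counts of all 229 clones form the
baseline population; the alternate population adds round(n_total·f_e)
events multinomially (uniform across clones); samples of 79 and 67 clones
are compared as above. The augmentation phrase "n(1 + f_e) additional
events" read literally would more than double the mean and contradict the
effect-size definition; the default adds n·f_e events, with the literal
reading available behind `literal_augmentation=True`. Because this
procedure inherits the empirical overdispersion of the pooled counts,
observed power is typically below the Poisson prediction.

## Construct expectations (`construct_expectations`)

Per-clone expectation: copies × (snm_rate + indel_rate) × length × T, with
copies = 2 explicit (the constructs are homozygous; the printed per-clone
numbers require diploid dosage). Multiplying by retained end-point clones
(67 D, 83 C, 79 W) gives expected mutant clones; the deactivating fraction
is the drive-component share of construct length (gRNA cassette 388 bp +
Cas9 4,890 bp). Composing the printed intermediates gives 0.099 expected
drive-deactivating D clones where 0.090 was printed alongside — the
published pair was presumably computed from unrounded intermediates under
slightly different component bookkeeping; this package reports the
composition of its own intermediates and does not target those two
numbers. The 6-fold uncertainty band divides/multiplies the expectation by
the genome-wide mutation-rate variation factor.

## Off-target scanning (`grna_offtarget`)

All NGG and NAG PAM occurrences on both strands are indexed; minus-strand
protospacers are reverse-complemented; sites whose 20-bp context runs off
the contig or contains N are dropped, and ambiguity codes other than N are
rejected. Similarity uses the MIT/Hsu single-site score: the product of
(1 − W[p]) over mismatch positions (W the 20 published per-position
penalties, PAM-distal to PAM-proximal), times a mean-pairwise-distance
penalty 1/(((19 − d̄)/19)·4 + 1) and a mismatch-count penalty 1/m², both 1
for fewer than two mismatches. A perfect match scores 1; note a single
mismatch at a zero-penalty position also scores 1 — a property of the
published weights, retained deliberately. NAG sites are scored with the
same weight table as NGG, with the PAM class recorded so users can filter.
Window similarity (max by default, mean optional) feeds an OLS regression
of normalized rate contrasts r = (R_s − R_W)/(R_s + R_W) on similarity,
optionally with PAM density as covariate; r is NaN (missing), not 0, when
both rates are zero.

## Problem sizes and tolerances in the shipped tests

The test suite exercises the caller against ground truth on 200
genome-scale clones (~37,500 markers each), recovers the simulated rate on
a 95-line cohort within 10%, checks bootstrap coverage over 200 replicate
cohorts, p-value calibration at 1,000 null draws, and the power curve at
1,000 simulations per grid point — sizes chosen so the full suite runs in
a few minutes on one CPU while keeping Monte-Carlo standard errors well
inside the asserted tolerances. Toy examples use a 1 Mb, 4-chromosome
genome, where overlap between the large terminal events is common; rate
recovery there is a few percent low by design (the interaction corrections
are out of scope), which the examples note.

## Known limitations

- The detection correction assumes the configured iLOH length model and
  ignores event-event interactions (merging, terminal overlap).
- The caller cannot distinguish whole-chromosome LOH from chromosome loss
  without coverage data; such events are only flagged.
- The Wasserstein Monte-Carlo null is O(n_mc × n log n) per chromosome;
  exhaustive enumeration is only feasible for tiny samples.
- MIT/Hsu scores rank site similarity; they are not calibrated cutting
  frequencies (no CFD or learned models).
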