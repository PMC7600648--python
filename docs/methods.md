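# Methods

## Mass bookkeeping

Peptide masses are monoisotopic sums of in-chain residue compositions
plus one water. The element table fixes ¹H, ¹²C, ¹³C and ¹⁶O at the
4-decimal values 1.0078, 12, 13.0033 and 15.9949 so that the three
diagnostic constants of the labeling design reproduce their defining
arithmetic digit for digit:

* Arg→canavanine shift: 15.9949 − 12 − 2×1.0078 = **1.9793 Da**
  (canavanine = Arg with one side-chain CH₂ replaced by O);
* third-to-first isotopologue spacing: 2×(13.0033 − 12) = **2.0066 Da**;
* conflict gap: their difference, **0.0273 Da** (27.3 mDa).

All other isotopes carry full-precision CIAAW 2019 masses. A consequence
of the truncation is that absolute peptide masses differ from a
full-precision calculation by up to ~1 mDa for ordinary peptides (e.g. the
Gly residue computes to 57.0214 rather than 57.0215, and the heavy-Arg
shift to 10.0079 Da); this is irrelevant at the precision of every
downstream quantity, which depends on mass *differences* built from the
four fixed values. Ions are charged with the proton mass 1.00728 Da
(standard positive-ESI convention; nothing downstream is sensitive to the
choice between the proton and the ¹H atom at the tolerances involved).

Canavanine and heavy Arg carry internal one-character symbols (`c`, `h`)
used only inside mass computations. PSM tables never contain them: a
record's sequence uses the 20 standard letters and a separate
`site_states` field assigns `H`/`L`/`CAV` to each Arg position in order.

## Resolvability model

The peak model is Gaussian. The resolution setting `R` is FWHM resolving
power specified at m/z 200, decaying as 1/√(m/z), so the full width at
10% maximum at a given m/z is

    FWTM = 1.822 · (m/z) / (R · sqrt(200/(m/z))),   1.822 = sqrt(ln10/ln2).

A canavanine variant and the A+2 isotopologue of the unmodified peptide
are called **resolved** when FWTM is *strictly* below the conflict
spacing 27.3 mDa / z; ties count as unresolved (conservative). The
required resolution of an ion is the smallest setting on the grid
10⁴…10⁶ (step 10⁴) that resolves it, with an `inf` sentinel when none
does; closed-form, the threshold scales as (m/z)^{3/2}·z.

`fine_isotope_envelope` aggregates isotopologue abundances by nominal
increment (A, A+1, A+2, …) via convolution of per-element natural
abundance distributions; ¹³C-vs-¹⁵N fine splits within one increment are
not resolved because the conflict in question operates at the A+2 level.
Centroids are placed at mono + k·1.0033 Da, which reproduces the 27.3 mDa
gap between the light A+2 and canavanine A+0 exactly.

`render_overlap` draws the summed Gaussian profile of two envelopes
(σ = FWTM / (2√(2 ln 10))) and flags the pair resolved when a local
minimum exists between the closest cross-envelope centroids. This valley
criterion is intrinsically *weaker* than the FWTM rule: FWTM ≈ 4.29 σ,
while a valley between two peaks persists down to separations ≈ 2 σ, so a
pair the FWTM rule declares resolved always shows a valley, but a valley
can appear at roughly half the FWTM-required resolution. The test suite
asserts the one-sided implication rather than a two-sided equivalence.

## Incorporation quantification

Records are first filtered to PEP ≤ 0.01 (inclusive) with at least one
Arg/canavanine site. The default **site convention** treats every
Arg/canavanine site of every record as one observation carrying the
record's full intensity as weight; identification shares are observation
fractions and intensity shares are weight fractions, computed within each
run and then averaged (mean ± SD, ddof = 1) across a condition's
replicate runs. With a single run the SD is reported as absent (NaN),
never as zero. Under this convention the CAV intensity share is an
unbiased estimator of the per-site occupancy π when response factors are
equal — each variant's intensity is proportional to its state-frequency
product, and summing over the variants of an s-site peptide gives CAV
weight s·π out of total s. A **peptide convention** (classify a record by
its single pure state, error on mixed records) is available for
comparison; identification shares count records (PSMs), with
deduplication by sequence left to the caller.

Variant pairing matches, per (sequence, run), the all-heavy variant with
every variant carrying exactly one CAV and heavy elsewhere; light-Arg or
multi-CAV records never pair. When a variant was observed as several
features (e.g. charge states) the most intense feature represents it.
Pair summaries report the median heavy/CAV intensity ratio both over all
pairs and deduplicated by sequence (median of per-sequence medians).
Retention-time deltas are tested with a two-sided Wilcoxon signed-rank
test and charge changes with an exact sign test (α = 0.05); both are
paired and distribution-free, and both are skipped with a notice below
six pairs. In the generator both members of a pair share the peptide's
charge and RT center, so the simulated charge-change table is degenerate
at zero and the sign test returns p = 1 by convention.

Top3 protein abundance is the mean of the three most intense proteotypic
peptides (mean of two when only two exist); proteins with fewer than two
proteotypic peptides are excluded. A peptide's intensity is the maximum
over its features by default (`sum` available). Canavanine-labeled vs
unlabeled protein abundances are compared with a two-sided Mann–Whitney U
test. Set enrichment is a per-term hypergeometric upper tail with
Benjamini–Hochberg control at FDR 0.05 over user-supplied annotations.

## Motif search

Sites are expanded to 11-residue windows (±5, `-` padding past protein
termini; padding is excluded from both numerator and denominator of
position frequencies). Discovery is iterative and greedy: at each step,
for every unfixed (position, residue), the binomial upper-tail
probability of the foreground count given the background frequency is
computed; the smallest p is fixed if p < 10⁻⁶ and its count ≥ 20 (the
recommended motif-x-style defaults), both sets are filtered to matching
windows, and the step repeats. Completed patterns are emitted, matching
windows are removed from both sets, and the search restarts; the empty
list is the valid "no enriched motif" outcome. Ties break by smallest p,
then leftmost position, then alphabetical residue, making the search
deterministic. Backgrounds are used in full, without subsampling. A
residue absent from the background at a position receives the
pseudo-frequency 1/(n_bg+1) rather than zero.

## Synthetic experiments

The generator emulates a heavy-Arg pre-labeled canavanine chase: random
protein sequences drawn i.i.d. from human-like residue frequencies
(Arg 5.6%, Lys 5.7%), digested with LysC — cleaving C-terminal to every
Lys *including* Lys-Pro, which is precisely why LysC suits this design:
Arg/canavanine stay internal to peptides — with up to 2 missed cleavages.
Only peptides of 7–35 residues are observed, mimicking a search engine's
identifiable window, and missed-cleavage products are down-weighted by
0.2 per missed site (digestion is efficient). Each Arg site draws a state
from the condition's (π_H, π_L, π_CAV); one record is emitted per state
variant with joint frequency above a floor (10⁻⁴), with intensity

    protein abundance × peptide ionization factor × variant frequency
    × state response product × log-normal noise,

protein abundance ~ LogNormal(15, 1.5) (arbitrary units), peptide factor
~ LogNormal(0, 0.8), noise σ = 0.25. Records below the detection limit
(default 10⁴) are dropped. Retention time is a Kyte–Doolittle
hydropathy proxy mapped onto a 100-min gradient with 0.3 min noise;
charge (1–4) depends on peptide length; canavanine variants inherit the
peptide's RT center and charge, reflecting the absence of chromatographic
and charge effects of the substitution. A misassignment rate (default 0)
flips each reported site state to one of the other two uniformly,
modeling false-positive state calls; ground truth keeps the
pre-misassignment states row-aligned with the table.

Default conditions are the four study arms (heavy-Arg 48 h, light-Arg
48 h, canavanine 24 h and 48 h, three runs each) with occupancies set to
the intensity shares such an experiment yields (π_CAV = 0.0583 at 24 h,
0.1263 at 48 h; residual light Arg ~1–4% reflects incomplete heavy
pre-labeling, modeled directly through π_L rather than a turnover model).
The default canavanine response factor is 0.9 — a mild
ionization/detectability deficit consistent with heavy/CAV pair ratios
running slightly above the pure frequency ratio (1−π)/π. Property and
acceptance scenarios that test estimator recovery set the response to 1
and the detection limit to 0, where the closed forms hold exactly.

What the generator does *not* emulate: real peptide sequences (windows
are i.i.d. residues, so motif null results on simulation do not preclude
motifs in real proteomes), chromatographic peak shapes, co-isolation,
search-engine scoring, and protein turnover kinetics linking the 24 h and
48 h time points (they are independent conditions here). Passing tests
demonstrate correctness of the estimators under the generative model, not
properties of any particular deposited dataset.

## Numerical and design choices

* Everything stochastic flows from one integer seed through
  `numpy.random.default_rng`; fixed seeds give byte-identical outputs
  (tables are written with stable float formatting).
* Tables are tab-separated UTF-8 with headers; positions are 1-based
  inclusive everywhere; readers report 1-based line numbers on error.
* Degenerate inputs raise explicit errors or notices (zero-observation
  condition, single run, mixed-state record under the peptide convention,
  groups too small to test) rather than silent zeros.
* Problem sizes in the acceptance script — 25 simulated proteins, three
  runs, ~14,000 Arg-site observations — were chosen as the smallest scale
  at which Monte-Carlo error on the recovered occupancy is well inside a
  percentage point.

## Limitations

* The FWTM constant 1.822 and the 1/√(m/z) resolving-power decay encode a
  Gaussian Orbitrap peak model; other analyzers need a different
  `ResolutionModel`.
* The incorporation estimator assumes canavanine does not change
  ionization efficiency when interpreting the intensity share as site
  occupancy; the response factor quantifies exactly this assumption in
  simulation.
* Identification-share metrics depend on the detection limit and are not
  occupancy estimates; they are reported because they are the standard
  companion metric, not because they are unbiased.
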