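# Methods

This note documents the models, parameter choices and numerical
conventions behind `sipautotroph`, and what the synthetic-data tests
do and do not demonstrate about real data.

## DIC assimilation rates

The rate engine converts end-point δ¹³C of particulate organic carbon
(POC) into a dissolved-inorganic-carbon (DIC) assimilation rate via
the standard delta-notation chain: δ¹³C (‰ vs VPDB) → isotope ratio
R = (δ/1000 + 1)·R_VPDB with R_VPDB = 0.0112372 → ¹³C atom fraction
n = R/(R+1) → rate = (POC_t·n_t − POC₀·n₀)/t · (Ca+Cs)/Cs. The factor
(Ca+Cs)/Cs undoes the dilution of the added ¹³C tracer (Cs, µmol/L)
in the ambient DIC pool (Ca), so the result is assimilation of *total*
DIC in µmol C L⁻¹ day⁻¹. Assumptions: the added bicarbonate is treated
as fully labeled and instantaneously mixed; no isotope fractionation
during uptake; no CO₂-system speciation (DIC enters as measured
totals).

**Detection limit.** Measured rates are only as good as the δ¹³C
reading, whose analytical precision is 0.1 ‰ (configurable as
`delta_precision`). A bottle whose δ shift is smaller than one
precision unit is flagged BDL (below detection limit); the reported
detection limit is the rate a shift of exactly one precision unit
would imply at unchanged POC. Computed rates more negative than minus
the detection limit are rejected as inconsistent inputs; smaller
negative excursions clamp to BDL. All arithmetic runs at full floating
precision; rounding happens only in the report layer (2 decimals for
rates ≥ 0.1, 3 below).

**Replicates.** The three tracer treatments of one condition behave as
biological replicates; `average_replicates` reports their mean and
sample standard deviation (n−1 denominator) over non-BDL entries, and
"ND" when every replicate is BDL. Only means are treated as firm
summaries; dispersion conventions vary between reports, so the sd is
informational.

## Gradient analysis

Profiles are (density, 16S copies) curves, strictly increasing in
density with ≥ 3 fractions. Normalization is min-max ("scaled between
0 and 1"), which is idempotent and order-preserving; a flat profile is
an error. The peak is the argmax fraction with ties resolved toward
the heavier density (the physically expected direction for labeled
DNA). Window classification uses half-open intervals [lower, upper)
so a boundary density belongs to the heavier window; the default
windows L = [1.690, 1.712), H = [1.715, 1.735), UH = [1.735, 1.760)
g/mL suit the synthetic band model below and must be set per study for
real gradients, where boundaries are placed by inspecting the
profiles. Fraction selection takes the contiguous run of k = min(3,
available) fractions (override k ∈ {1,2,3}) maximizing summed copies
within a window, ties again heavy; this is verified against exhaustive
enumeration. The cross-feeding control declares label transfer
negligible exactly when the ¹³C+¹⁵N peak is strictly heavier than the
¹³C-only peak. Single-peakedness is checked by requiring the profile
to be non-decreasing then non-increasing after a 3-point median
smoothing; violations warn rather than fail, since a bimodal
community profile still has a well-defined argmax.

## Labeling calls

The qualitative SIP interpretation — a labeled taxon's relative
abundance holds or rises from light to heavy, an unlabeled taxon's
falls sharply — is quantified with two thresholds on the H/L ratio:
unlabeled at ≤ 0.5 (a two-fold decline, mirroring the two-fold
convention used for KO enrichment) and labeled at ≥ 0.8 ("similar or
higher"); between them the call is ambiguous. Taxa below an abundance
floor (0.001) in both fractions are "insufficient". L = 0 with H > 0
is labeled with an infinite ratio sentinel. The UH/L ratio is reported
as corroborating evidence only; the verdict rests on H vs L. Table
calls first drop taxa below 0.5 % relative abundance in every
fraction, the usual screen for SIP amplicon heat maps. No statistical
test is attached to a single-replicate ratio. Calls are monotone in H
and invariant to common rescaling of a taxon's abundances.

## Gene and MAG abundance

Catalog-gene abundance is read-rate normalization: G_k = (r_k/L_k) /
Σ_i(r_i/L_i), with r_k mapped reads and L_k gene length (nt; units
cancel). G sums to 1, zero-read genes get 0, and the measure is
invariant to sequencing depth. Taxon aggregation sums G at a requested
rank, optionally excluding genes unclassified at the kingdom level
(the convention for read-taxonomy summaries) and optionally
renormalizing the included taxa. MAG relative abundance is the
proportion of uniquely mapped, correctly paired reads out of total
reads; mapping itself is upstream of this package.

## KO ternary classification

Each KO's per-million abundances (a₁, a₂, a₃) across three libraries
are classified with fold threshold f = 2: core iff max/min < f (all
positive); enriched(i) iff aᵢ ≥ f·max(others); diluted(i) iff
f·aᵢ ≤ min(others); otherwise unclassified. Comparisons are written
multiplicatively so zeros are safe — a KO present in exactly one
library is enriched there. The three named rules do not cover every
triple (e.g. (1, 1.5, 2.5)), hence the explicit unclassified category.
When enriched and diluted both fire (e.g. (1, 3, 9)), enriched takes
precedence. Boundary semantics: exactly two-fold is enriched/diluted,
not core ("less than two-fold" is strict; "at least two-fold" is
inclusive); the diluted rule mirrors the enriched rule at the same
two-fold margin, a documented choice. Classification is scale-
invariant per KO and equivariant under library permutation. Ternary
coordinates are the barycentric shares aᵢ/Σa; the scatter is drawn
directly with matplotlib (a short barycentric projection).

## Synthetic-data generators

**Gradients.** Unlabeled double-stranded DNA bands at buoyant density
1.660 + 0.098·GC g/mL; full ¹³C substitution adds +0.036 g/mL and full
¹⁵N a further +0.016 g/mL — standard SIP physical values, configurable
because real shifts scale with the degree of labeling. Each population
contributes a Gaussian band (default σ = 0.003 g/mL) evaluated on the
fraction-density grid; per-fraction copies get lognormal multiplicative
noise (qPCR-like error structure). The number of fractions and their
densities are free parameters (the demo uses 31 fractions at 0.003
g/mL spacing, a typical gradient fractionation).

**Tracer incubations.** The rate equation is run forward: the ¹³C
inventory of POC grows by rate·t·Cs/(Ca+Cs), POC itself by rate·t
(all fixed carbon retained in POC — the simplest mass-conserving
closure, stated as an assumption), and the end-point atom fraction is
converted back to δ¹³C before Gaussian noise (sd 0.1 ‰, the IRMS
precision) is added to both δ readings. Under this closure the
end-point atom fraction is bounded by max(n₀, Cs/(Ca+Cs)) and can
never overflow. Defaults mirror the incubation design this package
targets: 3 mM added bicarbonate (Cs = 3000 µmol/L), Ca = 2000 µmol/L
(vent-water DIC scale), POC₀ = 10 µmol C/L, δ₀ = −25 ‰, t = 1 day.

**KO tables.** Core KOs get three values within a < 1.24-fold spread;
enriched (diluted) KOs sit exactly `fold` above (below) the more
extreme of the two other libraries, whose own spread stays under
1.57-fold; `fold` must exceed the configured threshold. Output is on a
per-million scale via a single common factor (mean library total =
10⁶). Columns are deliberately *not* re-closed per library: the
remainder of each library is the unannotated fraction of its catalog,
and re-closing would distort the planted cross-library ratios (with
only enriched-in-one KOs, closure would cancel the enrichment
exactly). Classify such tables with `normalize=False`. The generator
verifies planted recovery at zero noise before returning.

**Taxon tables.** Relative abundances are compositional: each
fraction's column sums to 1, which pins the L-mass-weighted mean of
all H/L ratios at exactly 1. Two consequences are embraced rather than
hidden: (a) a community of only unlabeled taxa cannot show a two-fold
decline for every taxon and is rejected with an explanatory error;
(b) planted contrasts must survive closure, so the generator starts
from an 8-fold raw labeled/unlabeled contrast and doubles it until the
closed table reproduces every planted verdict (a deterministic loop;
labeled taxa's heavy-fraction multipliers are kept within 1.15× of
each other so the all-labeled community still calls labeled).

**What passing tests show.** Planted-truth recovery demonstrates the
estimators are correct inverses of the generating models at the stated
noise levels. Real data differ in ways the generators do not emulate:
partial and heterogeneous isotope incorporation (bands between L and
H), gradient compression and drift, compositional noise from finite
sequencing depth, chimeric/contaminant taxa, and KO abundance
correlations across libraries. Results on real tables therefore depend
on window placement and threshold choices, which is why every
threshold lives in `RunConfig` and is recorded in output provenance.

## Problem sizes and numerics

The tracer-recovery study uses 1000 simulated incubations with true
rates log-uniform over 10–1000× the detection limit (≈ 1.8×10⁻⁴ to
1.8×10⁻² µmol C L⁻¹ day⁻¹ at the default design), a span bracketing
the low-rate regime where IRMS noise matters; at exactly 10× the
detection limit a single bottle's relative error sd is ~14 %, so
recovery quality is a property of the rate span, not of one point.
Gradient selection is cross-checked on 1000 random profiles of 3–30
fractions; KO invariances on 10 000 random triples. Hypothesis-based
property tests run seeded. Ties in argmax/selection break heavy;
half-open window intervals make classification a partition; config
invariants (window ordering/disjointness, 0 < θ_unlabeled ≤ θ_labeled,
fold threshold > 1) are enforced at construction and violations name
the field.

## Known limitations

No qSIP-style per-taxon atom-fraction-excess estimation; no gradient
formation physics; no CO₂-system chemistry; no sequence-level
simulation (reads, genomes); KO annotation and read mapping are
upstream. The replicate-dispersion column is a sample sd and may not
match other reports' dispersion conventions.
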