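# Methods

## Scoring model

The fuzzy analytical method implemented here is a weighted multi-criteria
scoring scheme, not a general fuzzy-inference system: there are no rules or
t-norms, only scaling, fuzzification, weighted aggregation and centroid
defuzzification.

**Scaling.** Each sub-criterion's raw values are min–max mapped onto the
fuzzy scale [0, 10] using bounds pooled over *all* conditions and
replicates, not per condition — pooling is what makes scores comparable
across conditions. The transform is direction-aware: for the single cost
criterion (hardness) the mapping is reversed so that 10 always denotes the
best observed performance. Values exactly at a pooled bound are snapped to
exactly 10 or 0 rather than recomputed through the division, so that
"pooled best" compositions are exact in floating point.

A criterion whose pooled minimum equals its maximum is uninformative; every
value maps to the neutral score 5.0 and a warning is emitted. Failing
instead would let a constant criterion block an otherwise valid analysis,
and any non-neutral choice would arbitrarily push conditions toward best or
worst.

**Grades.** The six performance grades A…F are triangular membership
functions with apexes at 10, 8, 6, 4, 2, 0 and feet at the neighbouring
apexes, i.e. the unique symmetric equal-spacing partition of [0, 10] into
six grades. This makes the memberships a Ruspini partition (they sum to 1
at every score), which in turn makes defuzzification exact interpolation:
a single datum's score survives the grade round-trip unchanged. The grade
set is configurable (`grade_set` block in the criteria config, any ≥ 2
strictly decreasing apexes in [0, 10]); the partition property is preserved
by construction because membership is computed by linear interpolation of
grade indicators on the apex knots.

**Unequal data.** Each datum carries `weight / n` of its criterion's
weight, where `n` is the criterion's datum count *in that condition*. This
is the only apportionment under which a complete default condition's 108
data (6 instrumental × 3 replicates + 3 sensory × 30 panelists) exhaust the
100-point weight budget exactly, and under which a 29-panelist condition
still carries its full criterion weight. A datum-count mismatch against
`expected_n` is therefore a warning, not an error.

**Defuzzification.** The aggregated grade-mass vector is normalised by its
total weight *before* the dot product with the grade representative values
(the apexes by default). Normalising first keeps single-grade masses exact
(no `(10·w)/w` rounding) and makes the overall index invariant under any
positive rescaling of all criterion weights.

**Ties.** Conditions with overall indices equal to within 1e−9 share the
better rank (competition ranking), are flagged, and appear in condition-id
order, so output is fully deterministic.

## Numerical conventions

Equality assertions use 1e−9 absolute tolerance; criterion weights are
validated to sum to 100 within 1e−6 for the default library entry point.
Config files whose weights total something other than 100 load with a
warning instead of an error: the index is weight-homogeneous, so any
consistent positive weighting ranks identically, and rejecting such
configs would contradict that invariance. Negative assay concentrations
(absorbance below the blank) pass through with a warning — min–max scaling
tolerates them, and clipping would silently distort the pooled bounds.

## Measurement formulas

Rehydration capacity is `100 (w2 − w1)/w1` percent. TPC and TFC are read
off their published linear standard curves (`y = 0.471x − 0.0146` for
gallic acid at 725 nm; `y = 0.2408x + 0.1632` for quercetin) by exact
inversion; the curves' slopes and intercepts are taken as given, never
refitted. The TFC sources disagree on the read wavelength (420 nm in the
protocol, 725 nm in the curve caption); wavelengths are metadata only and
do not enter the arithmetic. Total anthocyanin is
`[(A535 · V · 100)/(0.2 · m)]/98.2` with V the extract volume (mL) and m
the sample mass (mg); the 0.2 mL aliquot, the ×100 dilution and the 98.2
divisor (an extinction-coefficient factor) are kept verbatim inside the
formula rather than parameterised, for fidelity to the published protocol.

## Synthetic data generator

The generator emulates the study design: a 3 × 3 × 3 factorial
(baking-powder 0.1/0.3/0.5 %, temperature 25/50/60 °C — room temperature
coded as 25 °C, only the ordering matters — time 10/20/30 min), three
Gaussian instrumental replicates per physical/bioactive criterion and 30
panelist scores per sensory attribute, drawn from a latent Gaussian,
rounded to the nearest integer and clipped to the 1–9 hedonic scale. One
seeded generator drives each `simulate` call; no global state.

Effect means are additive in rank-coded factor levels (−1/0/+1), with one
quadratic term letting springiness peak at the middle baking-powder level.
The *directions* of the shipped slopes follow the reported trends: higher
temperature and longer soaking depress rehydration; hardness falls with
baking powder and soaking time but rises with temperature; all three
bioactive contents fall with every factor, dominated by the baking-powder
effect; sensory scores rise with baking powder and soaking time. The
*magnitudes* are synthetic — no numeric means or SDs are published for
this design — and were chosen analytically so that the planted best
condition (0.1 % baking powder, room temperature, 30 min) separates from
its nearest competitor by ≥ 2 standard deviations of the overall-index
noise; the realised margin under the defaults is ≈ 2.9 SD, giving ≥ 95 %
rank-1 recovery across seeded simulations. One slope (a small positive
soaking-time effect on flavor) has no reported direction and is a free
synthetic choice. The shipped magnitudes must not be read as effect-size
estimates.

What passing tests on this generator show: that the pipeline's accounting,
invariances and ranking behaviour are correct under the assumed data
structure (independent Gaussian noise, additive effects, honest
replication). What they do not show: robustness to features of real
sensory/instrumental data the generator omits — panelist-level biases and
correlations, heteroscedastic or skewed assay noise, factor interactions,
batch effects, or missingness mechanisms.

## Problem sizes

Default analyses run the full 27-condition design (2,916 records); the
recovery suite repeats the complete generate-and-rank cycle over 200 seeds.
Property tests use randomly generated instances of 1–27 conditions with
1–5 data per cell, checked against an independently written per-datum
brute-force oracle.

## Known limitations

- The ranking is relative by construction: min–max scaling means an index
  of 10 is "best observed", not an absolute quality statement, and adding
  or removing a condition can change every score.
- Only linear (triangular, neighbour-footed) grade partitions are
  supported; trapezoidal or overlapping non-Ruspini grade sets are out of
  scope.
- Weights are taken as given; there is no pairwise-comparison elicitation.
- The sensory generator produces exchangeable panelists; it cannot test
  panelist-effect corrections because it contains none.
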