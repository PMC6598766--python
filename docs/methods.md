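# Methods

## The screening cascade

The pipeline models a whole-organism rescue screen run at a single
concentration (25 µM) with three embryos per well. Each embryo's in
situ staining is an ordinal score 0–3 (0 = full rescue, 3 = no effect),
so a well sum lies in 0–9. The decision cascade is:

1. **Primary categorisation.** Well sum → category: A 0–2, B 3–4,
   C 5–6, D 7–8, E 9; a well with dead or severely abnormal embryos is
   F (toxic); a well with no embryos found is G (potentially
   corrosive). Only the A boundary (≤ 2) is fixed by the assay
   definition; B–E edges are configuration (`RunConfig.category_bins`)
   validated to partition 0–9 exactly once. The toxicity rule defaults
   to "any dead embryo marks the well toxic" and can be relaxed to a
   majority rule.
2. **Hit rule.** Category A–C compounds are retested twice (nine
   embryos total). A compound is a hit iff the mean of its three well
   sums falls in category A–C *and* no individual well sum exceeds 7.
   Averages are kept exact and rounded only at reporting (two
   decimals). A toxic or empty retest fails the compound outright;
   fewer than three tests flags it incomplete.
3. **Counter screen.** Hits are assayed for restoration of the myelin
   marker around the posterior lateral line ganglion, twice (six
   embryos); the average of the two well sums is binned: rescue
   (> 3.5), no rescue (> 1.5 – 3.5), down-regulated (≤ 1.5). Upper
   edges are inclusive. The down-regulated bin catches compounds that
   suppress both markers — presumptive global transcription inhibitors,
   i.e. false positives of a down-regulation primary assay.
4. **Mechanism classification.** Counter-screen rescuers are re-screened
   on the strong (protein-truncating) allele, which cannot make the
   receptor: a compound that still rescues (sum ≤ 7) must act
   downstream of the receptor; one with no effect (sum 9) is a
   candidate receptor-level agonist; sum 8 or missing data (ND / DE
   codes) is inconclusive. The count-based rule for sum 8 reproduces
   the bundled hit table's 10/12/19 split exactly.
5. **Duplicate reconciliation.** For compounds present in both
   libraries, the absolute difference of their score averages is binned
   {0, 1–2, 3–6, 7–9} with the integer labels as inclusive upper
   edges. Where a compound was never retested the primary well sum
   stands in for the nine-embryo average (`triage.screen_average`).

## Chemistry conventions

Standardisation keeps the largest organic fragment, normalises
functional groups and neutralises charges where valence permits (RDKit
`rdMolStandardize`); no tautomer canonicalisation. It is idempotent,
which the tests assert across the fixture structures. Fingerprints are
binary 2048-bit Morgan, radius 2 (the ECFP4 convention); Tanimoto is
computed on explicit bit-index sets, with the both-empty case defined
as 0.0 so all-pairs matrices stay total. Bemis–Murcko scaffolds are
ring systems plus linkers; acyclic molecules map to the empty scaffold
and are tallied separately rather than counted as a scaffold. Duplicate
detection compares full 27-character InChIKeys (all three blocks), so
enantiomers with distinct stereo layers do not pair.

## Layout

Clustering is Ward's method on d = 1 − Tanimoto (the standard transform
for fingerprint similarities; the choice matters little at the display
level). Leaf order is the plain dendrogram traversal — no
optimal-leaf-ordering pass. Ward heights are checked for monotonicity
and any inversion is logged rather than raised, since 1 − T is not
Euclidean in general. Polar coordinates place compound i at angle
2πr_i/n (r_i its leaf rank) with seeded uniform angular jitter strictly
inside 45% of the inter-compound spacing — bounded so jitter can never
reorder compounds along the circumference — and at a ring radius fixed
by category (A innermost through G outermost, equally spaced,
configurable width) with radial jitter within ±30% of the ring width.
The similarity network connects pairs with T strictly greater than the
threshold (default 0.5, per the "over 0.5" rule); cluster extraction
returns connected components of at least five members, size-descending
with smallest-member tie-break.

## Statistics

SSMD is β = (μ₁ − μ₂)/√(σ₁² + σ₂²) with unbiased (n−1) standard
deviations by default (the σ notation is ambiguous; population SDs are
a flag away via `GroupStats.from_scores(ddof=0)`). Both-zero variance
returns 0 for equal means and a signed-infinity sentinel otherwise.

The LD50 model is a two-parameter sigmoid on log₁₀ concentration,
P(death) = F(slope·(x − m)), F logistic by default (probit available),
with binomial deaths per concentration; LD50 = 10^m. The model is
parametrised directly in (m, slope) so the 95% CI is read off the
profile likelihood of m at the χ²₁ cutoff (profile scanned on an
81-point grid over the data range ± 2 decades, endpoints refined by
root-finding; slope bounded in [10⁻³, 100], which also keeps the fit
finite under complete separation, where the estimate lands inside the
bracketing dilution step). All-dead or all-alive data raise a
non-identifiability error. On well-behaved data the estimate agrees
with an independent binomial-GLM route (statsmodels) to three
significant figures, which the tests check.

Calibration is established by simulation at the screening design — 16
embryos per concentration, an 8-point 1.5-fold dilution series
bracketing the true value (3.0–34.2 µM around an LD50 of 10 µM): with
a true slope of 4 per decade (acute mortality curves are steep —
observed screens go from 0% to 100% mortality within one or two
1.5-fold steps, implying slopes well above this), 200 replicates give
95%-CI coverage ≈ 0.95 and median |relative error| ≈ 8%; at a shallow
slope of 2 the coverage remains ≈ 0.93. These numbers are recomputed by
the test suite, not quoted.

Ear-width normalisation is the plain ratio of ear-to-ear width to head
width; scale-invariant, which is the property the tests pin.

## The synthetic screen

The generator emulates the study conditions: libraries of 1000 and
2000 compounds, 5% of the smaller library duplicated into the larger
(exact count, new plate positions, same structure and activity class),
compounds arrayed in columns 2–11 of 96-well plates. Chemistry is
template grafting: six scaffold families (dihydropyridine-, xanthine-,
flavone-, steroid-, 2-arylbenzimidazole- and quinolinone-like cores)
each decorated with ~12 small substituents, so within-family Tanimoto
stays above the 0.5 network threshold by construction; the remainder
are random chain-plus-ring singleton fillers (15% acyclic). Activity
classes are drawn per compound from proportions 0.01 / 0.01 / 0.01 /
0.01 / 0.91 / 0.05 over {downstream agonist, receptor agonist,
ear-specific, transcription inhibitor, inactive, toxic}; family members
instead inherit their family's planted class with probability 0.8
(structure–activity coherence). Scores are drawn per embryo from a
categorical distribution that puts mass 0.1 on the adjacent scores of
the class/assay base score; embryo death is Bernoulli per embryo
(0.005 background — routine husbandry loss — and 0.9 under toxic
compounds). One global seed fans out to per-stage substreams
(structures, classes, screen noise) so stages re-run independently and
the full simulate-then-triage run is bitwise reproducible.

What the generator does *not* emulate: concentration–response of the
ordinal scores (a single 25 µM design; dose–response lives in `stats`),
partial-rescue classes that would populate categories B–D heavily,
plate-position or batch effects, compound purity differences, and
empty (category G) wells. Passing recovery tests therefore show the
decision logic is implemented correctly and is robust to ordinal noise
and sporadic death — not that the thresholds are optimal for any real
assay.

## Problem sizes and numerical choices

The test suite runs the zero-noise end-to-end check at the full
3000-compound scale (a few seconds; scoring is arithmetic) and the
oracle comparisons at n ≤ 100, where brute force is instant. The LD50
calibration uses 200 replicates. The moderate-noise recovery check is
locked to seed 42, where agonist hit recall is ≥ 0.9 — the dominant
loss being wells failed for background embryo death under the strict
any-death toxicity rule, which is the intended behaviour of that rule,
plus occasional retest averages drifting past a bin edge.

Known limitations: category B–E boundaries beyond the A ≤ 2 rule are
conventions (configurable) rather than assay-fixed; the mechanism rule
treats a strong-allele sum of 8 as inconclusive wholesale rather than
judging per-embryo patterns; scaffold and duplicate counts on real
vendor catalogues depend on the standardisation pipeline used and will
differ slightly between implementations; and the LD50 profile CI is
clipped to the scanned range (data range ± 2 decades) for pathological
designs.
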