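# zfscreen

Hit triage and chemoinformatics for zebrafish whole-organism rescue
screens.

## The problem

In a phenotype-rescue drug screen, mutant zebrafish embryos (here, for
the adhesion GPCR Adgrg6, a regulator of inner-ear morphogenesis and
Schwann-cell myelination) are arrayed three per well against a compound
library, and whole-mount in situ hybridisation staining for a marker
gene is scored on an ordinal 0–3 scale per embryo — 0 meaning the
compound restored wild-type-like expression, 3 no effect. From these
noisy ordinal scores the screen has to decide, compound by compound:
did it rescue; does it hold up on retest; does it act on the pathway or
just suppress transcription globally; and does it act downstream of the
receptor or plausibly at the receptor itself?

`zfscreen` implements that decision cascade and the chemoinformatics
that organises its results:

- **triage** — well sums 0–9 → categories A–G (A: sum ≤ 2, the
  strongest rescue; F toxic; G no embryos found); the hit rule over a
  primary test plus two retests (nine embryos: average in category A–C
  and no single well sum > 7); counter-screen classes from the
  myelin-marker (*mbp*) average over six embryos (rescue > 3.5,
  no-rescue 1.5–3.5, down-regulated ≤ 1.5); mechanism classes from the
  strong (truncating) allele re-screen — score sum ≤ 7 ⇒ acts
  *downstream* of the receptor, sum 9 ⇒ *receptor candidate*, sum 8 or
  missing data ⇒ *inconclusive*; duplicate-score reconciliation across
  libraries.
- **chem** — structure standardisation, 2048-bit Morgan fingerprints of
  radius 2 (ECFP4-equivalent), Tanimoto similarity T(A,B) = |A∩B|/|A∪B|,
  Bemis–Murcko scaffolds, InChIKey duplicate detection.
- **layout** — Ward clustering on d = 1 − T, polar scatter coordinates
  (angle from dendrogram leaf rank, ring radius from screen category),
  similarity networks (edge iff T > 0.5, strictly) and cluster
  extraction, heatmap ordering.
- **stats** — SSMD β = (μ₁−μ₂)/√(σ₁²+σ₂²); a two-parameter logistic (or
  probit) mortality model on log₁₀ concentration whose `fit()` returns
  the LD50 with a 95% profile-likelihood CI; dose–response score
  tables; ear-width normalisation.
- **synth** — a synthetic-screen generator: two overlapping libraries
  with planted scaffold families and activity classes, simulated wells
  with ordinal noise and embryo death, and recovery metrics against the
  planted ground truth.

## Worked example

The package bundles the screen's 41 confirmed hits (compounds that
rescued both the ear marker and the myelin marker in the hypomorphic
mutant) with their strong-allele score sums. Re-deriving the mechanism
split:

```python
>>> from zfscreen.io import hit_table_records
>>> from zfscreen.triage import mechanism_report
>>> records = hit_table_records()
>>> report = mechanism_report(records)
>>> report["counts"]
{'downstream': 10, 'receptor_candidate': 19, 'inconclusive': 12}
>>> {lib: sum(d.values()) for lib, d in report["per_library"].items()}
{'S': 29, 'T': 12}
```

Of the 41 hits, 10 also rescued the strong allele (they must act
downstream of the receptor — including colforsin, an adenylyl-cyclase
activator, fr24 sum 0.00), 19 had no effect on it (candidate
receptor-level agonists, including the gedunin-family compounds), and
12 were partial or lacked data. 12 hits came from the Tocris library
(plate prefix T), 29 from Spectrum (S).

A full synthetic screen from the shell:

```sh
zfscreen simulate --seed 5 --n-a 1000 --n-b 2000 \
    --library-out lib.csv --wells-out wells.csv --truth-out truth.csv
zfscreen triage --wells wells.csv --library lib.csv \
    --out triage.csv --report-out report.json
zfscreen mechanism --triage triage.csv --out mechanism.json
zfscreen chem network --library lib.csv --threshold 0.5 --out net.graphml
```

Other verbs: `chem scaffolds`, `chem duplicates`, `layout polar`,
`stats ssmd`, `stats ld50`. For example,

```sh
$ zfscreen stats ssmd --mu1 2 --sigma1 1 --mu2 0 --sigma2 1
{"beta": 1.414213562373095}
```

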