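# Methods

## The measurement and its model

A protein-microarray RNA-binding screen measures, for each spotted protein,
the Cy5 fluorescence retained after incubating a labeled RNA on the slide.
The scanner reports per spot a foreground median (`F635`) and a local
background median (`B635`); the analysis unit is their ratio. Two design
facts shape everything downstream:

* every protein is spotted **in duplicate**, so each protein yields two
  ratios per scan;
* the overwhelming majority of proteins do not bind any given RNA, so the
  per-array ratio distribution is tightly centred at 1 with a sparse high
  tail — which is what makes a *global* Z-score a meaningful significance
  scale despite being computed from a mixture of binders and non-binders.

No between-array normalisation is applied: each scan is filtered against
its own ratio distribution, because absolute intensities vary with probe
labeling density and incubation conditions while the within-array ratio
structure does not.

## Hit calling

Per protein: `mean_ratio`, `min_ratio` over usable duplicates (spots with
scanner flag ≥ 0 and positive background), and
`Z = (mean_ratio − μ)/s` with μ and the **sample** (n−1) standard
deviation s taken over all non-control proteins on the array. At n ≈ 9,000
the ddof choice is numerically immaterial but is fixed for
reproducibility. Controls are excluded from μ and s: they are engineered
bright and would inflate the spread, masking true binders.

A hit requires `min_ratio ≥ 2.5` **and** `Z ≥ 3`, both inclusive. The
minimum (rather than the mean) over duplicates means a single bad spot
vetoes a call — the filter's conservatism against spot artifacts. Both
comparisons are inclusive; written protocols for this assay mix "greater
than" and "≥" phrasing, and the inclusive reading is adopted and fixed
here.

Sequence-nonspecific binding (poly-basic surfaces, chaperones, sticky
proteins) is handled by probing each locus's **antisense** transcript under
identical conditions and subtracting its hit set from the sense hit set.
The result is a binary proteins × RNAs matrix whose rows are the proteins
with at least one sense-specific interaction. Rows and columns are ordered
by agglomerative clustering with Jaccard distance on the binary profiles
and average linkage — a metric/linkage pair chosen because profiles are
sparse binary vectors where co-absence carries no signal; ties resolve
deterministically because rows enter in lexicographic order.

"Common binders" are ranked by the percentage of **all** incubations
(sense and antisense alike; every scan is a trial) in which the protein was
called, keeping those at ≥ 75 %. A protein flagged bad on one array still
counts that array in its denominator.

## Significance statistics

Replicate concordance is the Pearson correlation of per-protein mean
ratios over all proteins quantifiable in both replicates — not hits only,
so the statistic reflects the whole measurement, not the thresholded end
of it. Hit-set overlap and annotation-term enrichment are both one-sided
hypergeometric upper tails, `P(X ≥ k)`, equivalent to the one-sided Fisher
exact test (the only direction meaningful for replicate overlap or
over-representation). The enrichment background is the spotted-protein
universe, not the genome; annotation entries outside the universe are
dropped with a report. The conservative EASE variant (k−1 in the tail) is
available opt-in; the default is the plain hypergeometric because it is an
exactly defined statistic rather than an emulation of a web service's
settings. Multiple testing across terms uses Benjamini–Hochberg
(`statsmodels`), order-preserving.

## Labeling QC

Dye density converts the dye absorbance to picomoles via Beer–Lambert
(`A_dye / ε_dye` is molar concentration at 1 cm path) times the solution
volume, per µg RNA. The printed protocol formula omits the volume — an
absorbance is a concentration proxy and cannot yield an amount — so the
volume is an explicit argument (protocol default 16 µL); users whose
spectrophotometer reports path-normalised absorbance of a different
dilution must supply their own volume. Constants: ε_dye = 250 000,
ε_base = 8 250 M⁻¹cm⁻¹, A₂₆₀ dye-correction factor 0.05. The base:dye
acceptance window 700–1200 nt/dye is inclusive at both ends.

## Synthetic screens

The simulator exists so the entire pipeline can be exercised with exact
ground truth. All noise is multiplicative (Gaussian on the log scale), the
standard model for fluorescence intensities:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 9,125 | non-control features, duplicate-spotted |
| `n_blocks` / `block_columns` | 48 / 22 | sub-array geometry (~484-spot blocks) |
| `background_log_mean/sd` | 6.2 / 0.3 | log-normal B635 (median ≈ 490) |
| `nonspecific_log_sd` | 0.1 | log-ratio SD of non-binders |
| `nonspecific_shared_frac` | 0.5 | protein-intrinsic share of that variance |
| `duplicate_log_sd` | 0.05 | spot-to-spot noise |
| `control_f635` | 55,000 | fixed bright positive controls |

Per protein and scan the binding ratio is
`fold × exp(ε_intrinsic + ε_fresh)`, per spot it gains
`exp(ε_dup)`, and background is drawn per protein with its own per-spot
perturbation. The split of the non-specific variance matters only for
technical replicates: the intrinsic component (a protein's reproducible
stickiness toward a given RNA sample) is shared between replicates, the
fresh component is redrawn per array. Real replicate scans of this design
correlate strongly across *all* proteins, which a purely fresh noise model
cannot produce; at the default 50/50 split the simulated replicate r² is
≈ 0.85. Duplicate spots share the binding draw but not the spot noise, so
the min-over-duplicates filter is genuinely stressed.

When every noise SD is zero the arithmetic is arranged so that each
non-binder ratio is *exactly* 1.0 and each planted ratio is bit-exactly its
fold after the F/B division (products are nudged by at most a few ulp where
IEEE rounding would land one ulp under the constructed ratio) — so
threshold-fold plants are recovered exactly, not "up to rounding".

The default planted truth mirrors the structure of a published screen of
this design: 137 sense-specific interactions spread round-robin over 10
loci (folds cycling 2.5–8), 28 shared both-strand binders on every locus
(recovered as 100 % common binders and removed from the matrix by the
antisense subtraction), and 31 antisense-only binders — 196 distinct
binding proteins. Randomness is streamed per (seed, locus, strand,
replicate), so any single scan is reproducible in isolation and
byte-identical on re-simulation.

What the simulator does **not** model: spatial artifacts (gradients,
scratches, washing effects), spot-morphology variation, carry-over between
blocks, saturation, or any chemistry of labeling. Passing tests therefore
demonstrate the correctness of the statistical pipeline under a idealised
noise model, not robustness to the full failure modes of real slides —
those must be caught by the flag/QC fields the pipeline already honours.

## Problem sizes and numerical choices

The test suite runs the full study-scale recovery (9,125 proteins × 20
scans) once noise-free and twenty times under noise with planted folds ≥ 4
(the operating point at which near-certain recovery is the correct
expectation; folds at the 2.5 cutoff are missed about half the time by
construction, since noise is symmetric about the threshold). Smaller
layouts (300–2,000 proteins, 3 loci) are used wherever scale adds nothing.
Hypergeometric tails are validated exhaustively against exact integer
enumeration for every 2×2 table with universe ≤ 60.

Degenerate inputs are errors, not silent results: zero background, zero
ratio variance (a perfectly flat array has no Z-scale), fewer than three
shared proteins for a correlation, inverted QC windows, universes smaller
than the sets drawn from them. Spots flagged bad by the scanner are kept
at parse time and excluded at aggregation, so the exclusion is auditable
in logs; proteins losing both duplicates are reported and dropped.

## Known limitations

* Ties in clustering are resolved by input (lexicographic) order; a
  different but equally valid dendrogram rotation may order rows
  differently in other implementations.
* The common-binder denominator counts every incubation regardless of
  per-array spot quality.
* Enrichment assumes the annotation map is already closed over any
  ontology hierarchy (no graph propagation).
* The GPR reader targets the ATF 1.0 dialect with the standard required
  columns; exotic exports (alternate wavelength labels, locale decimal
  commas) are out of scope.
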