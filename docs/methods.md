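# Methods

## The Cartesian-plot model

Two cell populations are pre-labelled with spectrally distinct lipophilic
dyes (here called *green* for the cancer-cell population and *red* for the
fibroblast population), cultured alone (controls) or together (co-culture),
fixed, imaged, and segmented to per-cell integrated fluorescence, profile
area, and perimeter. Analysis is always per experiment; tables mixing
`experiment_id`s are partitioned first.

**Background.** A channel's background rate (fluorescence per unit area) is
estimated from the control population *not* labelled in that channel: the
red signal of green-labelled controls is background plus bleed-through,
never label, so `red_bg_rate = Σ red_raw / Σ area` over the summated green
controls (and symmetrically). Estimating a channel's background from the
population labelled in it would subtract signal. The correction
`corrected = max(0, raw − area × rate)` clamps at zero because both log
plots and the angular transfer metric require non-negative coordinates. A
`background_mode: none` escape hatch skips the subtraction.

**Normalization.** Each channel is rescaled so the corrected own-channel
median of the corresponding control population equals 100 normalized
fluorescence units (NFU). This makes classifications invariant to any
common rescaling of a channel (gain, exposure), which the test suite checks
end to end, and makes renormalization of already-normalized data the
identity.

**Classification bounds.** The "range" of a control population is the
closed interval between the trimmed minimum and trimmed maximum of its 100
sampled cells (`trim` cells dropped per tail as a fraction, default 0, i.e.
plain min/max; 0.01 resists outliers). Own-channel ranges are treated as
unbounded above: transfer adds only opposite-channel signal, so a
co-cultured cell brighter than any control in its own channel is still a
member of that population. If one population's bleed-through ceiling
reaches the other's own-channel floor, the five regions are ill-defined and
classification aborts with a diagnostic.

**The five populations.** With bounds `green_lo`, `red_bleed_hi`,
`red_lo`, `green_bleed_hi` and a cell at `(g, r)` in NFU:

| condition | label |
|---|---|
| g ≥ green_lo and r ≥ red_lo | uncertain origin |
| g ≥ green_lo and r ≤ red_bleed_hi | indistinguishable from green controls |
| g ≥ green_lo and red_bleed_hi < r < red_lo | green with some red label |
| r ≥ red_lo and g ≤ green_bleed_hi | indistinguishable from red controls |
| r ≥ red_lo and green_bleed_hi < g < green_lo | red with some green label |
| otherwise | unclassified |

Boundaries are closed toward the indistinguishable labels (conservative
toward "no transfer"), and the uncertain region takes precedence where both
own-channel floors are met. Cells below both floors are kept in an explicit
unclassified bucket, reported separately, excluded from five-group
percentages, and logged loudly.

**Exchange Units.** EU is linear in the angle θ (degrees) between a cell's
origin ray and the green axis: `EU = 50·(45 − θ)/45`, so the diagonal
(complete mixing) is 0 and the axes are ±50. Linear-in-angle is the minimal
reading of "angular divergence from the diagonal"; the anchors (0 on the
diagonal, ±50 on the axes) pin the map up to that choice. Cells
indistinguishable from a control are pinned to ±50 by their *group*; a
non-indistinguishable cell that happens to sit exactly on an axis keeps its
group and its computed ±50 value but falls in the adjacent open interval
when binned — the ±50 EU domains are defined by group membership, not by
value. A cell at the exact origin with an unpinned group has no angle; its
EU is NaN and it is excluded from EU summaries (logged). The seven EU
domains are `EU=−50`, `(−50,−30]`, `(−30,−10]`, `(−10,10]`, `(10,30]`,
`(30,50)`, `EU=50`.

**Orientation.** When an experiment's label orientation is swapped (donor
green instead of red), `flip_orientation` negates EU and mirrors groups and
domains so results align with the rest; it is an involution.

**Sampling caps.** At most 100 control cells per population and 1000
co-cultured cells enter an analysis; larger inputs are uniformly subsampled
under the run seed for reproducibility.

## Methylation channel

Nuclear anti-5mc fluorescence is divided by propidium-iodide fluorescence
of the same nucleus (cnf = 5mc/PI), cancelling DNA content (cell cycle,
aneuploidy); cnf is then scaled so the control fibroblast median is 100.
Outlier handling defaults to none — the median is already robust — with an
optional exclusion of control cells beyond `k` median absolute deviations
(k = 3 by default when enabled). cnf uses integrated nuclear ratios, which
equal per-pixel-mean ratios when the 5mc and PI masks coincide. The
methylation channel is purely a phenotype readout: attaching it changes no
classification or EU value.

## Segmentation

Per-channel foreground masks (automatic threshold by default, manual raw
thresholds via config) are united before connected-component labelling, so
a cell bright in either channel becomes one object. The automatic threshold
is Li's minimum cross-entropy on log1p intensity: punctate,
organelle-concentrated label is heavy-tailed, and a raw-scale Otsu
threshold lands above the diffuse body of dim cells and loses them
entirely. Objects under `min_size` (50 px default) are removed. Touching
cells can optionally be split by a distance-transform watershed (off by
default; adjacent cells are otherwise merged, as manual separation is the
usual practice). Perimeter uses the weighted boundary-step estimator;
digitized circularity of very small regions can slightly exceed 1 and is
reported unclamped with a warning. Nuclei are segmented from the PI channel
the same way and assigned to cells by majority mask overlap; multiple
nuclei in one cell are pooled (summed) before the cnf ratio. Channels are
assumed registered.

## Statistics

Mann–Whitney U compares cell groups within an experiment (exact null for
small untied samples, tie/continuity-corrected normal approximation
otherwise); the Wilcoxon signed-rank test compares paired per-co-culture
group medians across experiments (zeros dropped, exact for small n); the
paired t-test serves small methylation series. All tests are two-sided.
Pairs with a missing group are dropped listwise. No multiple-testing
correction is applied by default, matching the raw-threshold reporting
style of this assay class; Holm adjustment is available. Percentages in the
summary tables are taken against the total co-cultured cell count and
rounded half-away-from-zero to one decimal.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistics the analysis is sensitive to:

* **Own-channel fluorescence** is log-normal (log-sd 0.6, ≈1.5 orders of
  magnitude across a 100-cell population) — control populations show wide,
  skewed spreads best viewed on log axes. Default log-means 9.2 (green)
  and 9.8 (red, fibroblasts being larger and brighter).
* **Opposite channel** of a control carries additive background
  (0.5 units/px² default) plus bleed-through at 1% of an own-level draw.
* **Transfer** is predominantly donor (red) → acceptor (green): an acceptor
  transfers with probability 0.7 and receives a Beta(0.6, 2.4) fraction of
  a fresh donor-level draw — right-skewed, most recipients gain little and
  a few gain much, giving the continuous gradations of uptake seen in real
  co-cultures. Reverse transfer occurs at probability 0.05. The received
  fraction can be pinned to a constant for distribution-law tests.
* **Morphology** couples linearly to the received fraction: area ×(1+0.8a),
  circularity ×(1−0.45a) — direction (spreading, flattening) is what the
  assay reports; the linear form and slopes are stipulated. Perimeter is
  derived from area and circularity, so shape invariants hold by
  construction.
* **Methylation**: cnf is log-normal per population (medians 0.5 fibroblast,
  0.3 cancer, log-sd 0.25), and co-culture depresses fibroblast cnf by 40%.

Not modelled: dye chemistry and differential lateral membrane mobility of
the two dyes, cell motion, illumination inhomogeneity, camera noise, and
touching cells in the renderer (blobs are placed on a non-overlapping
grid). Passing tests therefore demonstrate correctness of the measurement
and classification pipeline under known ground truth, not robustness to
every imaging artifact of real monolayers.

Counts default to the analysis caps (100 + 100 controls, 1000 co-cultured)
and a donor mix of 0.5.

## Numerical choices and degenerate inputs

* Negative background-corrected fluorescence clamps to 0.
* Zero control own-channel median after correction aborts normalization.
* Trimming drops `floor(trim·n)` order statistics per tail; a trim leaving
  no cells raises.
* The classification predicates partition the non-negative quadrant exactly
  (property-tested against an independent predicate oracle, including
  points on boundaries).
* EU is computed with `atan2`; antisymmetry EU(g,r) = −EU(r,g) holds to
  1e−9.
* The renderer distributes each cell's integrated fluorescence exactly over
  its blob (uniform base plus concentrated puncta), so channel sums match
  the table by construction.

## Problem sizes

Test and acceptance runs use the study-condition sizes: 100 control cells
per population, 500–1000 co-cultured cells for recovery checks, 3000 for
dose–response bin medians, 10⁵ random points for the classification/EU
oracle sweeps, and 1000 replicates for the type-I-error calibration of the
three tests at n = 20–30.

## Known limitations

* The classification depends on control extrema; with trim 0 a single
  aberrant control cell can move a bound (the `trim` option exists for
  that).
* EU compresses all transfer information into one angle; two cells with
  very different absolute fluorescence but the same ratio score the same.
* The renderer is adequate for exercising segmentation, not for mimicking
  microscope optics.
* Exact reproduction of any particular laboratory's segmentations is not
  claimed; thresholds and the perimeter estimator are documented choices.
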