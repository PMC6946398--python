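# Methods

`fscclone` is a quantitative toolkit for clonal analysis of the *Drosophila*
follicle stem cell (FSC) lineage. It implements, on synthetic data, the full
chain of reasoning used to infer the number of active FSCs per ovariole from
mitotic-recombination lineage tracing: the combinatorics of the marking
systems, a stochastic ovariole simulator, clone-pattern classification,
closed-form lineage timing, clone-size-based inference of stem-cell number,
and 3D image-based clone-size quantification. This note documents the models,
their assumptions, the defaults, and the design choices made where the
procedure being reproduced was informal or interactive.

## Marker-combination models

Three marking schemes are built in.

* **LGR** — a dual-FRT scheme on chromosome II: GFP distal to FRT40A on 2L of
  one homolog and LacZ distal to FRT40A on the other; RFP distal to the 2R
  FRT site of the first homolog, nothing distal on the second. (The 2R site
  is named FRT42B in some sources and FRT42D in others; only the arm
  topology matters here, so a single 2R site is modelled.)
* **GFPNEG_FRT19A** — the standard negatively marked scheme: GFP distal to
  FRT19A on one homolog; clones are scored by loss of GFP.
* **MARCM_FRT19A** — a tubGal80 repressor distal to FRT19A; clones are
  GFP-positive because only repressor-free homozygous daughters de-repress
  the reporter.

The canonical frequency model is the *equal-genotype* assumption: each arm
independently ends up hom1/hom1, hom1/hom2, or hom2/hom2 with probability 1/3.
For LGR this yields 9 genotypes at 1/9 each and, through the dominance rule
(a marker is expressed iff at least one copy is present), 6 phenotypes at
1 : 1 : 1 : 2 : 2 : 2 (LacZ : GFP : LacZ+GFP : LacZ+RFP : GFP+RFP :
LacZ+GFP+RFP). Phenotypes are binary presence/absence; expression level is
not modelled.

Because LacZ and GFP are both on 2L, every genotype retains at least one of
them: `is_canonical_phenotype` flags RFP-only and triple-negative cells as
unreachable by FRT recombination. Such phenotypes in real data indicate a
non-canonical event such as heritable transgene silencing; the simulator
exposes silencing as a rate (below) rather than modelling its mechanism.

`chromatid_oracle` audits the equal-genotype assumption at the chromatid
level: two sister chromatids per homolog, an exchange at a site swapping the
site-distal segment between one chromatid of each homolog, and an explicit
sister-segregation rule. Under uniform pairing with random segregation, a
recombined arm stays heterozygous in half of the daughters (1 : 2 : 1 per
arm), *not* 1 : 1 : 1 — i.e. the equal-genotype model is a specific
assumption, not a consequence of the mechanics. The
`segregation="uniform_genotype"` mode reproduces the canonical model by
construction; `x_only` / `z_only` explore the segregation extremes. The
question of which assumption real tissue satisfies is left open, by design.

`recombinant_phenotype_distribution` conditions the equal-genotype model on
recombination having occurred (the ancestral fully heterozygous genotype is
excluded) and, for schemes that mark only one daughter class, keeps the
detectable class (the GFP-null daughter for negative marking; the
repressor-free daughter for MARCM).

## Ovariole simulator

The simulator is the package's synthetic-data generator. An ovariole is
`n_fsc` FSC lineages at the germarium's Region 2a/2b border, an effective
pool of transit (prefollicle) cells, and a chain of budded follicles. Time is
continuous in hours, t = 0 at the first heat shock; events (heat shocks,
follicle budding, synchronized division rounds, daily replacement/quiescence
draws, sampling) are processed chronologically from a single per-ovariole RNG
stream, so runs are reproducible bit-for-bit. `simulate_cohort` spawns one
substream per ovariole from a master `numpy` `SeedSequence`.

Published quantities used as defaults:

| parameter | default | meaning |
|---|---|---|
| `n_fsc` | 2 | active FSCs per ovariole |
| `cycle_h` | 9.6 h | follicle-cell division time |
| `follicle_cells_stage6` | 900 | cells per Stage-6 follicle |
| `transit_h` | 100 h | border-to-Stage-6 transit |
| `ovariole_clearance_d` | 8.5 d | transient-clone exit from the scored region (8–9 d transit) |
| `heat_shock_times_h` | 0, 8, 24, 32 | the 4 × 1 h regimen over two days |
| `sample_dphs` | 5…25 | the standard time course (days post heat shock) |

Quantities with no published value, chosen once as modelling defaults:
`budding_interval_h` = 12 h (a placeholder; the budding rate is not printed),
`transit_pool_size` = 6 effective labelable transit cells in the scored
region, `n_scored_follicles` = 3 (the convention of scoring the germarium
through the first 2–3 budded follicles), `germarium_cells` = 60 prefollicle
cells, `igs_induction_prob` = 0.05 (labeling of inner germarial sheath cells,
which produces the non-border anterior-cell classes). `induction_prob` is the
per-FSC labeling probability *per heat shock*; its default 0.05 puts roughly
a third of ovarioles in the FSC-clone class under the default regimen, and
the closed-form complement rule 1 − (1 − p)^l holds exactly for single-shock
regimens (which the tests use).

Processes:

* **Induction.** At each heat shock, each unlabeled FSC is labeled with
  `induction_prob`, drawing a phenotype from the recombinant distribution;
  each transit-pool cell likewise, creating a transient clone that covers a
  uniform 5–50% of one follicle and exits the scored region after
  `ovariole_clearance_d`. Transient clones spend their first 36 h inside the
  germarium before joining a follicle.
* **Background.** Per division round, each FSC and transit cell recombines
  spontaneously with `background_rate` (default 1e-4, keeping the no-heat-
  shock clone rate under ~2% over a week, as a reliable system should).
* **Silencing** (LGR only). Per division, with `silencing_rate`, a lineage
  heritably silences one currently expressed marker — the mechanism that
  produces RFP-only and triple-negative "impossible" clones.
* **Replacement.** Per day, with `replacement_rate`, one FSC is lost and its
  slot taken by the other lineage; a labeled loser's patch loses border
  contact and drifts out of the scored window — the replacement pattern.
* **Quiescence.** Per day per labeled lineage, with `quiescence_rate`, a
  labeled prefollicle cell stalls in the germarium (small-germarium patch)
  and later detaches into a disjoint downstream patch, producing the
  discontinuous pattern. This implements a hypothesis about the origin of
  discontinuous clones, nothing more.

**Follicle growth.** Each budded follicle is founded by one cell per active
FSC and grows to 900 cells. The default `polya` model is exchangeable
reinforcement (a new cell joins a lineage proportional to its current size),
sampled exactly through its de Finetti representation: founder shares are
Dirichlet(1,…,1) and counts are 1 + multinomial. With two founders a share is
uniform on (0, 1); since an ovariole's clone size is the mean over the three
scored follicles (founded independently), the per-ovariole clone-size SD is
≈ 28.9 / √3 ≈ 17 percentage points — the same order as the 14–18 point
spreads seen in real mosaic ovarioles. The `deterministic` model splits
equally (largest remainder) and is used for exact tests and for computing
expectations.

**Geometry is logical, not spatial.** Patches carry flags (border contact,
follicles spanned, per-follicle fractions, germarium-only) rather than
coordinates; contiguity claims in the scored region are qualitative, and cell
counts are bookkept so that patch counts plus background always sum to the
scored total.

What the generator does *not* emulate: subclone induction by repeated heat
shocks in dual-FRT systems, unequal fitness between marker classes, mechanical
or spatial structure of the epithelium, germline dynamics beyond the timing
parameters, and any fitting of replacement/quiescence/silencing rates to real
counts (they are free parameters). Passing tests therefore demonstrate
internal consistency of the analysis chain under neutral assumptions — not
that real tissue satisfies those assumptions.

## Clone-pattern classification

`classify_clone_pattern` assigns, per recombinant phenotype, one of five
categories with fixed precedence: discontinuous (border patch plus a disjoint
downstream same-phenotype patch) → fsc_persistent (contiguous border patch
spanning ≥ 1 budded follicle) → replacement (≥ 2 follicles, no border
contact) → small_germarium (all patches inside the germarium) → transient
(≤ half of one follicle, no border contact; also the fallback). Precedence is
a design choice — discontinuity is the decisive anomaly — as is evaluating
"half a follicle" on labeled-cell fraction rather than arc length. Two
boundary rules are worth noting: a border-touching patch that has not yet
contributed to a budded follicle classifies as small_germarium, and in a
single-phenotype system a transient clone coexisting with a persistent clone
necessarily scores as discontinuous (the patterns are genuinely
indistinguishable without lineage information).

Lineage diversity (`count_unique_lineages`) counts phenotype classes, not
patches: two disjoint same-phenotype patches are one class, and the
unrecombined background class counts when background cells are present. This
is the conservative reading of "uniquely labeled clones"; counting patches
instead would only raise diversity.

Frequency tables are Pearson-chi-square tested against predicted phenotype
distributions (`scipy.stats.chisquare`); the chi-square choice is ours — the
comparison being reproduced was descriptive.

## Timing model

`t = log2(P / l) · r` for `l` lineages dividing every `r` hours to reach `P`
cells, with the exact value and a nearest-hour rounding reported side by
side: (900, 2, 9.6) → 84.61 h ≈ 85 h, compatible with the ~100 h transit to
Stage 6, while (900, 16, 9.6) → 55.81 h ≈ 56 h. `population_after` is the
exact inverse. Early mitotic exit of the polar/stalk sublineage (which makes
real production slightly slower) is out of scope.

## FSC-number inference

Under neutral growth, one labeled FSC among `l` contributes 1/`l` of the
follicle epithelium in expectation, so `l̂ = 1 / mean(fractions)` over mosaic
ovarioles (non-mosaic ovarioles — "none" and "full" — are excluded, matching
the measurement protocol). Uncertainty is a seeded percentile bootstrap over
ovarioles (default 10⁴ resamples); no maximum-likelihood alternative is
attempted because the reciprocal-mean is the estimator implied by the
reasoning being reproduced. `implied_fsc_range` converts mean ± 2 SD of the
fractions to a range of `l` (lower fraction floor 1e-3; low end clamped to
≥ 1): a 50.1 ± 14.1% clone size implies roughly 1.3–4.6, i.e. one to four
active FSCs. The labeling complement rule 1 − (1 − p)^l inverts an observed
fraction of clone-bearing ovarioles to a per-FSC induction probability
(33.9% with l = 2 → p ≈ 0.187). Cross-condition clone sizes are compared with
Welch's t-test, Bonferroni-adjusted.

`CloneSizeModel` / `CloneSizeResults` wrap the estimator in a fit/summary
interface; `CloneSizeModel.from_records` applies the mosaic filter to
simulator records.

## Image-based quantification

`generate_stack` renders nuclei as isotropic Gaussian blobs
(σ = diameter / 4, diameter drawn from 2.0–2.25 µm unless fixed) at
rejection-sampled centres with a minimum spacing (default 2.6 µm), on a
(32, 96, 192)-voxel grid at (0.5, 0.25, 0.25) µm — a 16 × 24 × 48 µm volume
holding 200 nuclei. The clone-marker channel gives each nucleus a high or low
amplitude (600 ± 60 vs 60 ± 15) per its ground-truth label; both channels
get additive Gaussian noise. These stacks emulate the intensity structure of
two-channel confocal data, not its optics: no PSF anisotropy beyond voxel
size, no depth attenuation, no autofluorescence gradients — segmentation
scores on synthetic stacks are best cases.

`segment_nuclei`: Gaussian smoothing (0.4 µm) → Gaussian high-pass at 2×
the nuclear diameter (background subtraction) → Otsu threshold → distance-
transform watershed seeded at local maxima ≥ diameter/2 apart → volume floor
at 10% of the nominal nuclear sphere (Otsu keeps only the bright core of a
blob, so captured volumes sit well below nominal). Two guards return an empty
surface list on no-signal input: a flat image (dynamic range < half the
median) and an Otsu threshold below 5% of the dynamic range. The smoothing
scale, floor, and guards are exposed parameters whose defaults are justified
by recovery against the generator's truth tables (detection F1 ≥ 0.95,
centroid gate 1 µm by Hungarian assignment).

`fit_label_threshold` replaces the interactive scatterplot procedure with
Otsu on log mean intensities plus two-class Lloyd refinement (minimising
within-class variance), reporting an η² bimodality diagnostic; input with
η² < 0.5 is flagged unimodal and left unassigned rather than force-split.
`quantify_clone_fraction` counts surfaces below (negative marking) or above
(positive marking) the threshold within an anterior-posterior window; with
anterior-posterior along +x and voxel-centred µm coordinates.

## Problem sizes and numerical conventions

Simulated checks use 300 ovarioles for clone-size means (Monte-Carlo SE just
under 1 percentage point), 10⁴ for closed-form rate checks (SE ≈ 0.5 points),
and 10⁴ multinomial draws for classification round-trips; the segmentation
benchmarks use single 200-nucleus stacks. All stochastic paths take explicit
seeds (`numpy.random.default_rng`), cohorts use `SeedSequence` substreams,
and iteration orders avoid address-dependent containers, so identical seeds
give byte-identical outputs across processes. Follicle cell counts round
largest-remainder in deterministic mode and cap patch cells at the follicle's
unassigned remainder, keeping conservation exact. Probability sums are
validated to 1e-12; bootstrap CIs are clamped to contain the point estimate.

## Known limitations

The simulator's rare-pattern processes (replacement, quiescence, silencing)
are single-rate caricatures meant to generate the *patterns*, not their
kinetics; the equal-genotype marker model is an assumption whose chromatid
audit shows it is not forced by the mechanics; the synthetic image model is
intentionally idealized; and the category frequencies observed in real
tissue are empirical quantities this package uses only as fixture inputs —
nothing here claims to derive them.
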