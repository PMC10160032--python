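# Methods

## The generative model

The simulator is phenomenological: it reproduces the *contrasts* between
repair/bypass deficiency groups with the simplest per-lesion probability
model, not lesion chemistry or repair kinetics.

**Lesion formation.** Every dinucleotide site is examined once per strand.
Pyrimidine pairs (YY read 5′→3′ on either strand) acquire a CPD with
probability `λ_cpd` and a 6-4PP with probability `λ_64pp`; TA and TG
dinucleotides acquire a rare photoproduct with probability `λ_rare`.
Draws are independent Bernoulli — no dose–response or sequence preference
beyond eligibility.  A per-tumor lognormal exposure factor
(`exposure_sigma`, log-SD) scales all three rates together, so burdens of
the different photoproduct classes co-vary across tumors the way shared UV
dose makes them co-vary in real cohorts.

**Repair.** A lesion is removed by GG-NER with probability

    p_GG = gg_scale · g0 · (1 − γ_RT · rtRank)

where `rtRank ∈ [0,1]` is the within-contig quantile of the
replication-timing track at the site (0 = earliest = most accessible
chromatin).  On the transcribed (template) strand of annotated genes in
TC-proficient cells the lesion is instead *committed to the TC pathway*:
stalled transcription machinery shields it from global-genome sensing, and
it is removed with probability `t0 · h(e)`, `h(e) = e/(e + h_k)` saturating
with expression `e` (RPKM).  Past the transcription end site both the
shielding and the removal probability decay as `exp(−d/l_ext)`.  Upstream
of the TSS and on the untranscribed strand only GG-NER acts.

The shielding construction is the one deliberate departure from a purely
multiplicative two-pathway survival model.  If both pathways acted
independently on the template strand, the untranscribed/transcribed
mutation ratio (TRB) would algebraically cancel the GG-NER term and be
identical in GG-proficient and GG-deficient tumors — contradicting the
defining observation that losing GG-NER *raises* TRB (the untranscribed
strand loses its only repair while the template strand keeps TC-NER).
Exclusive template-strand commitment reproduces that, and makes the
transcribed-strand survival `1 − t0·h(e)` a group-independent baseline, so
the relative GG-NER efficiency estimator
`e_g = 1 − TRB_g / TRB_null` is exactly linear in `gg_scale` (the recovery
tests exploit this).  The cost is that weakly expressed genes have a
shielded-but-unrepaired template strand; their per-gene TRB can dip below 1.

**Translesion synthesis.** Surviving dimers mutate with probability
`mu_eta` (polymerase η present) or `mu_backup` (absent); the erring
position is the 3′ base with probability `beta_3prime`; an error at a
thymine is accepted with probability `t_accept_*` (η errs overwhelmingly at
cytosines, backup inserters also at thymines); the substituted base is then
drawn from a per-polymerase spectrum.  An accepted error at a CC dimer
becomes a CC>TT doublet with probability `dbs_prob`.  Rare TA/TG
photoproducts are bypassed near-error-free by polymerase η
(`mu_rare_eta`) but are strongly mutagenic without it
(`mu_rare_backup`), erring at the 3′ purine and producing TA>TT / TG>TT
changes — the T>A and C>A classes that distinguish bypass-deficient
genomes.

**Group presets** (packaged JSON, versioned with the package): sporadic
(all pathways active), `xpe` (`gg_scale` 0.4), `xpc` (`gg_scale` 0), `xpa`
and `xpd` (`gg_scale = tc_scale = 0`), `xpv` / `polh_ko` (repair intact,
`pol_eta` false, `beta_3prime` 0.97).

### Default parameters

| parameter | default | units / meaning |
|---|---|---|
| contig length × n | 1.5 Mb × 2 | toy genome, GC 0.42 |
| genes | 24, 6–14 kb | slot placement, ≥110 kb apart so ±50 kb flanks stay clean |
| expression | lognormal(2.8, 1.2) | RPKM-like; `h_k = 2` half-saturation |
| `λ_cpd`, `λ_64pp`, `λ_rare` | 0.035, 0.010, 0.012 | lesions per eligible site per strand |
| `g0`, `γ_RT` | 0.8, 0.9 | GG-NER baseline and RT coupling |
| `t0`, `l_ext` | 0.9, 13 kb | TC-NER removal; post-TES decay length |
| `mu_eta`, `mu_backup` | 0.25, 0.55 | dimer error probability per bypass |
| `beta_3prime` | 0.55 (η) / 0.97 (backup presets) | 3′ allocation of dimer errors |
| `t_accept_eta`, `t_accept_backup` | 0.05, 0.35 | error acceptance at T bases |
| `dbs_prob` | 0.20 | CC error → CC>TT doublet |
| `exposure_sigma` | 0.4 | per-tumor lognormal dose log-SD |

`g0`/`γ_RT` imply a latest/earliest mutation-fraction fold of ≈3.6 over 8
quantile bins (`implied_rt_fold` computes the closed form); `t0·E[h]`
yields group TRBs ordered sporadic < XP-E < XP-C with XP-A/XP-D at 1.
These values were fixed analytically from those target contrasts before
the analysis stages were run, and are not adjusted per experiment.
The relative CPD : 6-4PP mutagenicity per context is not constrained by
data; the two dimer types share one downstream model and their rate split
is a free, documented parameter.

**Quality annotations.** Caller-style features (CONTQ, SEQQ, STRANDQ,
TLOD) are drawn from a multivariate Gaussian "real" cloud; injected
formalin-artifact doublets (TG:CA>CA:TG) draw from a cloud shifted by
`separation_sd` (default 4) pooled SDs per feature.  The overlap of these
clouds — not the classifier — bounds achievable filter accuracy.

## What the simulator does and does not emulate

It emulates: group-specific trinucleotide spectra, strand asymmetries and
their expression dependence, replication-timing and TAD/chromatin
gradients with trinucleotide-opportunity structure, post-TES repair decay,
3′ dimer error bias, doublets, artifact feature clouds, and per-tumor dose
variation.  It does not emulate: read-level data (no FASTQ/BAM), copy
number or clonal structure, mutation hotspots or selection, sequence
preferences of lesion formation within eligible sites, repair kinetics in
time, or genome-scale context composition (the toy genome is an i.i.d.
draw).  Tests passing on simulated cohorts therefore validate the
*estimators* — that each statistic recovers the structure that generated
the data — not biological claims about real genomes.

## Analysis conventions and numerical choices

* Internal coordinates are 0-based half-open; VCF positions convert at the
  I/O boundary.  Track queries on uncovered territory return NaN, never 0.
* Adjacent same-sample SNVs at distance 1 merge into one doublet; runs of
  ≥3 merge greedily left-to-right with a warning (applied twice, the merge
  is a no-op).
* Mutation classes are pyrimidine-centric; the strand carrying the
  pyrimidine is the lesion strand.  A lesion on the template strand of its
  gene is "transcribed".  Genes overlapping on both strands are excluded
  from stranded analyses and counted.
* Opportunity counting: k-mers with N are excluded symmetrically from both
  mutation classification and opportunity counts.  For 4-mers the
  canonical representative keeps the orientation whose central
  dinucleotide is a pyrimidine pair (lexicographic minimum for mixed
  centers).
* Adjusted fractions use `rate_b = Σ_c (m_bc/o_bc)·w_c` with genome-wide
  context weights `w_c`; a mutation in a bin/context with zero opportunity
  raises an error (inconsistent inputs) rather than dividing.  Empty-bin
  pseudo-fractions in slope fits are opt-in (`pseudo=True`), never silent.
* "Equal size" replication-timing bins are equal covered territory; with
  fixed windows that is equal window counts.  Bin 1 is the
  latest-replicating bin, so repair gradients give negative log-slopes.
* TSS/TES meta-profiles tile ±50 kb in ten 10-kb bins; 1-kb intervals
  overlapping any other gene body are removed, and genes whose window
  leaves the contig are excluded and counted.  Post-TES significance is a
  per-bin one-sided binomial test of strand counts against 0.5 with
  Benjamini–Hochberg correction across bins (q = 0.05); the reported
  extent is the leading run of significant bins, so it is
  detection-limited: with ~10⁵ lesions per tumor it saturates near
  3·`l_ext`, where the decayed bias drops below noise.
* XR-style track normalization divides 1-kb interval means by the
  interval's per-strand dipyrimidine count (TT+TC+CT+CC substrate sites);
  a TT-only alternative is a one-line change in
  `dipyrimidine_window_counts`.  All ratio outputs are invariant to track
  scaling.
* POPAF thresholds treat the annotation as −log10 population allele
  frequency: "POPAF > 5" keeps variants with population AF < 10⁻⁵.
* The dimer-bias default context is ACCA (and ATTA for thymine classes):
  purine flanks make the central dimer register unambiguous, which an
  ACCT-style context would not (its 3′ T forms a second overlapping
  dimer).  The context is a parameter.
* NNLS refitting uses the active-set solver (scipy) — deterministic, with
  residual tolerance at machine precision, so exact mixtures refit to
  dissimilarity 0.  In `uv12` mode signatures are renormalized on the
  12-context subspace.  Classical MDS fixes signs by making the
  largest-magnitude loading positive; `pca_on_distance` (principal
  components of distance-matrix rows) is kept as a compatibility mode.
* The FFPE classifier follows the per-sample recipe: label CC>TT doublets
  true-like and TG:CA>CA:TG artifact-like; tune the soft-margin cost over
  {0.001…100} by cross-validated accuracy on a 25% subset (disjoint from
  the 50% training and 25% held-out subsets — enforced even though
  overlap would be easier); RBF kernel with bandwidth 1/n_features after
  standardization.  Two deliberate calibration choices: grid ties (common
  on separable samples) break toward the default cost 1, because extreme
  small costs underfit the decision function and coarsen the probability
  map; and probabilities come from isotonic regression on cross-validated
  decision values rather than a Platt sigmoid — with strongly separated
  classes the empirical posterior is a step, and the sigmoid's parametric
  ceiling caps confident true variants just below the 0.95 retention
  threshold.  The sigmoid remains available (`calibration="sigmoid"`).
  Missing pileup features impute by per-feature training median.
* Consequence calls use one canonical transcript per gene (longest CDS;
  ties and overlaps resolved deterministically), 2-bp splice windows at
  intron edges counted damaging, and codon-aware doublet application
  (worst consequence across touched codons).  The toy transcriptome
  stamps valid ORFs into gene exons so translation is well-defined.
* TMB denominators default to analyzable (post-mask) territory; a
  full-genome flag mirrors pipelines that report per total genome length.

## Problem sizes

The shipped tests and the acceptance script run on 3-Mb toy genomes with
24 genes (60 in a gene-dense layout used for strand-count-hungry
recoveries), 6–12 tumors per group and ~0.8–1.3 × 10⁵ lesions per tumor
(~4–20 × 10³ mutations, group-dependent).  These sizes were chosen so
that each parameter recovery has ≥ 2–4σ resolution under its stated
tolerance; estimator formulas contain no genome-scale constants, so they
apply unchanged to full genomes.

## Known limitations

* The template-shielding repair model is binary (a gene either commits
  its template strand to TC-NER or not); graded commitment would soften
  the sub-unity TRB of weakly expressed genes at the cost of breaking the
  linearity of the GG-efficiency estimator.
* The bootstrap TRB interval resamples mutations, ignoring between-tumor
  heterogeneity; for small cohorts the per-sample table is the honest
  summary.
* Post-TES extent is a detection threshold, not an unbiased estimate of
  3·`l_ext`; under-powered cohorts shorten it and an unlucky far-bin
  fluctuation can extend it by one bin.
* `NumericTrack.window_means` loops over intervals in Python; fine for
  bedGraph-scale toy tracks, not for dense genome-wide signal (a bigWig
  reader is intentionally out of scope).
* The megabase density PCA assumes comparable per-window mappability
  after filtering; no GC or coverage correction is applied.
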