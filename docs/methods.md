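# Methods

This note documents the models, numerical choices and limitations behind
each stage of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signatures and consensus aggregation

A signature is the vector of per-gene differential-expression z-scores of
one perturbation in one cell line versus controls (LINCS L1000-style;
~978 landmark genes in the default synthetic panels). Replicates are
collapsed with a MODZ-style weighted consensus: with replicate vectors
z₁…z_r and a correlation measure c (Spearman by default, Pearson
selectable), replicate i receives weight

    wᵢ ∝ max(w₀, Σ_{j≠i} c(zᵢ, zⱼ)),   Σ wᵢ = 1,

with floor w₀ = 0.01. The floor keeps weights positive, so a replicate
anti-correlated with the rest is driven to (nearly) zero weight rather
than a sign-flipping negative one. Consequences worth knowing: with two
replicates the weights are always ½/½ (their mutual correlations are
equal), and when *every* replicate's correlation sum falls at or below
the floor — e.g. one strong outlier among only three replicates can drag
all three sums down — the floor equalises the weights and the consensus
degrades gracefully to the plain mean. Median and mean aggregation are
available as simpler alternatives. The exact variant used to produce the
packaged target-panel consensus values is not recomputed here; that
table is treated as a fixture input.

Similarity between signatures is a correlation over the genes both
signatures carry (intersection semantics, never imputation; at least 3
shared genes required). Spearman with average ranks for ties is the
default — z-score signatures are heavy-tailed and a rank statistic is
robust to a few extreme genes. An optional `top_n` restricts the
comparison to the query signature's largest-|z| genes, the usual
connectivity-map asymmetry; without it the measure is symmetric.

## The network screen

Because the compendium lacks a knockdown of the protein of interest
itself, a proxy gene whose silencing collapses the same network stands
in (NPM1 for FOXM1), plus knockdowns of the proxy's interaction partners
for guilt-by-association evidence. Per compound and cell line the screen
records the direct correlation with the proxy knockdown and the
best/mean correlation over partner knockdowns. Cell lines missing either
signature are skipped, not zero-filled — zero-imputation would silently
penalise sparsely profiled compounds beyond what the support rule
already does.

Support and qualification: a compound is supported in a cell line when
its direct correlation reaches τ (default 0.3, Spearman) and qualifies
as a candidate when supported in at least 4 cell lines. The 4-line rule
is fixed by the screening design; the value of τ is a free parameter
exposed as a flag, as is the choice of statistic. The composite score is
the mean over supported lines of (direct + λ·best-indirect), λ = 0.5 by
default; max rather than mean feeds the indirect term because a single
strong partner match *is* the association signal. The score is monotone
in every correlation, and unqualified compounds are pinned to −∞ so they
can never outrank a qualified one. A trained ranking (random forest on
the flattened per-cell-line feature vectors plus support count,
seed-controlled, requiring ≥ 2 compounds per class) is an opt-in
alternative; the deterministic composite score is the default behaviour
and the reference for the recovery tests.

Direction convention: both compound and knockdown signatures are
treatment-versus-control, so a compound that phenocopies the knockdown
correlates *positively* with it.

Panel tables collapse all signatures of each chosen perturbation
(across cell lines and replicates) to one consensus value per panel
gene. Candidate comparison reports universality (panel genes with
z ≤ −1.0; the threshold must be negative and is configurable) and
potency (mean panel z), ordering by universality first.

## Codirectional DE signatures

DE tables (gene, log2 fold change, p, optional FDR) are consumed, not
fitted — count normalisation and dispersion modelling belong to the
upstream DE pipeline. Thresholding keeps genes with fold change ≥ 2
(inclusive: `log2FC ≥ 1` exactly at the boundary) and FDR strictly
below 0.1, optionally restricted to protein-coding biotypes before
thresholding. Both thresholds are flags. When a table lacks an FDR
column it is computed with the Benjamini–Hochberg step-up
(q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·n/j, capped at 1); when a supplied column
disagrees with the recomputation by more than 1e−6 the supplied column
wins with a logged warning, since upstream pipelines may have corrected
over a different universe. Gene identity is exact string equality — no
symbol conversion.

The codirectional signature of two models is up∩up and down∩down;
up/down-discordant genes are reported separately, and the accounting
identity |significant in both| = |up both| + |down both| + |discordant|
holds by construction. Whether the upstream "protein-coding universe"
also reflects an expression floor is not modelled; an optional flag can
be layered on by filtering the input table before the call.

## Preranked GSEA

The ranked list is strictly ordered (ties in the ranking value broken by
gene id, lexicographically) so every run of the algorithm sees the same
order. The ranking metric is a choice of the caller; `log2_fc` is the
default and signed −log10 p is selectable — neither is claimed to be
canonical for any particular study. Walking down the list, the running
sum gains |r|^w / N_R at members (w = 1 by default; N_R normalises hit
increments to 1) and loses 1/(N − N_hit) elsewhere; the ES is the value
of maximal |deviation|. At w = 0 this is the unweighted two-sample KS
statistic up to sign, which the tests verify against scipy's
`ks_2samp`. If every member has ranking value 0 the hit weights
degenerate to uniform.

Significance uses gene-label permutation — the only null available for
preranked input — with one label shuffle per permutation shared by all
sets (1000 by default, minimum 100). NES divides the ES by the mean
|null ES| of the same sign; the nominal p is the same-sign null tail
fraction with add-one smoothing; the FDR q is the canonical pooled-null
ratio (same-sign tail fraction of all normalised null ES over the
same-sign tail fraction of observed NES), capped at 1. Sets outside
[15, 500] members after restriction to the ranked universe are dropped.
For permutation ES only the 2k running-sum candidate extremes (just
after/before each hit) are evaluated, which makes 1000 permutations of a
2000-gene list take a few seconds. Fixed seed ⇒ bit-identical output.
Gene-set collections are user-supplied GMT files; no collection is
bundled.

## Colocalization

Images are one cell per image, 24-bit RGB split losslessly into
channels. Thresholds are strictly-greater-than on the 8-bit scale and —
by design — constant across all images of an experiment; the pipeline
applies one (t_green, t_red) pair per run. Because "Manders
coefficient" is ambiguous between variants, both are reported and
labelled: thresholded M1 = Σ green over (G∩R) / Σ green over G (and the
mirror M2), and the intensity-weighted overlap coefficient
Σ g·r / √(Σ g² Σ r²) over the union support G∪R (pixels dark in both
channels never enter the support, so background cannot inflate the
value). A coefficient whose denominator mask holds fewer than 10 pixels
is reported as not-applicable rather than as an unstable ratio; 10 is a
documented default, not a measured constant.

The image generator plants `spot_count` red disk puncta, places a fixed
number of green pixels (200 by default) so that exactly
round(f·200)/200 of the green intensity lies on red-positive pixels,
and draws one blue nuclear ellipse; at zero added noise the thresholded
M1 equals the planted fraction up to the 1/200 placement granularity
(≤ 0.0025, well inside the ±0.02 recovery tolerance the tests assert).
What the generator does *not* emulate: point-spread blur, uneven
illumination, autofluorescence, cell-shape variation — passing recovery
tests demonstrate the estimator's correctness on clean geometry, not
robustness to real microscopy artefacts.

## Small-sample statistics

Mann–Whitney U uses midranks (0.5 credit per tie). For pooled samples of
≤ 25 observations the null distribution of U is exact: a dynamic
programme over the multiset of (doubled) midranks counts all C(n+m, n)
equally likely group assignments by rank sum, which is identical to full
enumeration but polynomial-time, and handles ties exactly. The two-tailed
p doubles the smaller one-sided tail and caps at 1 — for two groups of
four with complete separation this gives 2/70 ≈ 0.02857 — with
summed-tails as a selectable alternative. Above 25 observations a
tie-corrected normal approximation with continuity correction takes
over, flagged `exact=False`.

Pfaffl ratios accept efficiencies as fold-per-cycle (validated to
(1, 2.2]) or as percent (auto-detected by magnitude and logged; 95 ↦
1.95). With several reference transcripts the per-reference ratios are
combined by geometric mean by default (a mean-ΔCt alternative is
provided); the geometric mean is symmetric in the references and
reduces to the single-reference formula when they agree.

## Synthetic study conditions

The screen generator's defaults are the study regime: 978 landmark-like
genes, the seven densely profiled cell lines (A549, MCF7, VCAP, HA1E,
A375, HCC515, HT29), 49 pure-noise decoy compounds plus one planted
inhibitor, 3 partner genes, mixing weight α = 0.7. The mixing rule
z_compound = α·z_kd + √(1−α²)·ε keeps the planted compound's marginal
standard normal while its expected correlation with the knockdown is α;
partner knockdowns share the network response at weight 0.5. Replicates,
when requested, mix a shared latent signature with replicate noise at
s = 0.3 under the same variance-preserving rule. Noise is i.i.d.
standard normal per gene — gene–gene correlation structure, batch
effects and dose–response are deliberately out of scope, so recovery
results quantify the method under clean independence assumptions, not
LINCS covariance.

The DE generator defaults to the studied regime (16 275 protein-coding
genes; 577 shared-up, 687 shared-down, 77 discordant, 200
model-specific significant genes per model; |log2FC| ≈ 2 jittered
upward; planted p ~ U(0, 1e−4)); null fold changes are clipped inside
the 2-fold boundary so planted counts are recovered exactly by
construction rather than with high probability. The ranked-list
generator places a 30-gene set uniformly within the top (or bottom) 10%
of a 2000-gene list.

The recovery test suite runs screens at a reduced scale (300 genes, 20
decoys, 20 seeds per mixing weight, with the support gate opened so
ranks are comparable across α) and asserts median planted rank 1 at
α = 0.6 degrading monotonically toward α = 0; the acceptance script
runs one full-scale screen. All generators are bit-reproducible under a
fixed seed.

## Pipeline and determinism

The run config is validated against an explicit schema (unknown keys
and missing inputs are reported by name); stages execute in a fixed
dependency order, all randomness derives from the configured seed, and
the JSON report echoes parameters, input checksums and headline outputs
so that two runs of the same config differ only in the timestamp.

## Known limitations

- The screen's correlation threshold τ, the partner list and the
  training-label construction for the classifier ranking are free
  parameters of the design, not derived constants; defaults are
  documented above and exposed as flags.
- Real perturbation compendia have replicate-count heterogeneity,
  dose/time structure and strong gene–gene covariance that the
  generators do not model.
- The GSEA FDR is the canonical pooled-null estimate; it is known to be
  conservative for small collections and is not a per-set adjusted
  p-value.
- Image analysis assumes pre-delimited single-cell images; no
  segmentation or automatic (Costes-style) thresholding is provided.
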