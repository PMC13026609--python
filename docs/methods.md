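# Methods

`kinsnp` is a workbench for pairwise kinship inference from medium-density
autosomal SNP panels (~10,000 markers), of the kind used in forensic
investigative genetic genealogy. It contains a pedigree simulator that
produces genotype pairs with exactly known identity-by-descent (IBD), two
IBD-segment detectors, five classifiers that map detector output (or raw
genotypes) to a degree of kinship, and an evaluation harness. This note
records the models, the defaults and the reasoning behind the open design
choices.

## Degrees of kinship

A relationship of degree *d* has expected kinship coefficient
φ = 2^−(d+1) (parent–child and full siblings are both degree 1, first
cousins degree 3, fourth cousins degree 9). Unrelated pairs carry the
internal ordinal 10, adjacent to degree 9, so that "within t degrees"
margin arithmetic works on one scale; reports render it as "unrelated".
The default catalogue holds 18 related pedigree types spanning degrees 1–9
(lineal, collateral, half- and removed-cousin types) plus unrelated; each
pedigree's exact kinship is verified against the recursive path-counting
coefficient in the test suite.

## Synthetic panel

`generate_panel_fixture` lays out loci over the 22 GRCh38 autosomes
proportionally to physical length (~2,875 Mbp total; default 10,030 loci,
mean spacing ~0.29 Mbp). Alternate-allele frequencies model a
*kinship-optimised* panel: minor-allele frequency uniform on [0.30, 0.50]
with random ref/alt orientation. Kinship panels select strongly
heterozygous markers, and this choice reproduces the background behaviour
reported for such kits — an unrelated pair shows ~2–4 long identical-by-
state (IBS) runs surviving the length filter, a mean of ~40–50 Mbp of
false "sharing" under the run-based detector, with roughly a quarter to a
third of unrelated pairs above 50 Mbp. A broader frequency spread (e.g. a
Beta(2,2)-like MAF distribution) floods the run detector with ~10× that
background, because long concordance runs assemble preferentially across
stretches of low-MAF SNPs where opposite homozygotes are rare.

What the generator does **not** emulate: linkage disequilibrium between
panel markers (founders are drawn in linkage equilibrium), population
structure or admixture, and genotyping artefacts beyond i.i.d. missingness
and error. Background IBS in real panels is therefore somewhat
*understated* here, and passing accuracy floors on synthetic cohorts does
not guarantee them on real profiles.

## Pedigree simulation

Founders are drawn under Hardy–Weinberg equilibrium from the panel
frequencies. Gene dropping propagates labelled founder haplotypes through
each pedigree; every meiosis places crossovers as a Poisson process with
intensity 1 per 100 cM along the genetic map, with no crossover
interference. True IBD1/IBD2 intervals between the two targets are
computed exactly by intersecting the four haplotype mosaics (IBD state =
size of the label matching between the two pairs of haplotypes).

The default map is uniform in cM/Mbp but scaled to **3,500 cM** total —
the sex-averaged autosomal length of human pedigree maps — rather than the
1 cM/Mbp rule of thumb (~2,875 cM). Total genetic length controls segment
counts and with them the tails that matter here: at 3,500 cM, ~28–30% of
simulated fourth-cousin pairs share no autosomal IBD at all, matching the
theoretical ~30% for ninth-degree relatives; a 2,875 cM map inflates that
to ~38%. Sex-specific maps can be supplied as map files; the uniform
default ignores sex. Omitting interference slightly widens the
realised-kinship distributions relative to an interference-aware
simulator; the main visible consequence is a few points of accuracy at the
fourth degree and beyond.

Noise defaults to 10⁻³ per SNP for both missingness and genotype error;
an erroneous call is replaced by one of the two other dosages uniformly,
so an error never reproduces the truth.

## IBD-segment detection

Both detectors treat a locus as *concordant* when the pair shares at least
one allele there — i.e. anything except opposite homozygotes, the only
genotype pair impossible inside a true IBD tract absent error. Genotype
*equality* is deliberately not used: IBD1 tracts are only half-identical,
and the purity statistic of the windowed detector is defined by
allele-sharing as well. Missing calls neither break nor extend runs and
are excluded from all counts.

**A1 (concordance runs).** Maximal concordant runs per chromosome are
filtered by physical length (< 10 Mbp removed), then by segment
informativity. Informativity is calibrated on the *unfiltered* base runs
of every reference pair: Ic(i) counts the runs containing SNP i, and
MI(i) = med(Ic)/Ic(i) over SNPs with Ic ≥ 1, so rarely-shared SNPs count
for more; a segment's informativity Is is the sum of MI over its loci, and
segments with Is ≤ 50 are removed. Finally segments are trimmed against
masked regions — by default the panel's own coverage gaps wider than
5 Mbp, where no marker can support a segment — and each remnant,
re-anchored to its outermost SNPs, survives only if still > 10 Mbp
(strict) with Is > 50.

**A2 (windowed kinship scan).** Windows of L = 80 consecutive SNPs (one
window per starting SNP; a short chromosome yields one window) are scored
by the robust kinship-coefficient estimator restricted to window loci;
windows with φ > 0.23 are stored, merged by ordinal overlap, and merged
segments with allele-sharing purity p < 0.95 are dropped. Inside an IBD1
tract the expected window coefficient is 0.25, barely above the 0.23
threshold, so the window statistic keeps the heterozygote-count
designation whose small positive bias at window scale (~+0.03 for L = 80)
the threshold is calibrated to; the opposite designation pushes IBD1
windows below threshold and shatters long segments.

Neither detector separates IBD1 from IBD2, and both overestimate segment
ends (a run extends to the nearest discordant SNP beyond the true
boundary, ~1–3 Mbp per side at this density). The classifiers tolerate
this because their reference models are built with the same detector, so
the bias cancels.

## Classifiers

Four methods classify a pair from its detected segments; one works on raw
genotypes. All argmin/argmax ties resolve toward the *higher* degree
ordinal — the conservative direction, claiming less relatedness.

* **Mean total length.** Nearest per-relationship mean MS(r) of the total
  detected length.
* **Gamma distributions.** A gamma model (shape k by maximum likelihood,
  scale θ = mean/k so the fit preserves the sample mean) is fitted to the
  pair's segment lengths and to each relationship's pooled reference
  segments; profiles are the densities on the integer grid 1–150 Mbp, and
  the pair takes the relationship with the smallest mean absolute profile
  difference. Pairs with fewer than two segments (or identical lengths)
  *abstain*; abstentions are first-class results that score as incorrect.
* **Conditional probability.** P(R | S) learned on 50 Mbp bins of total
  shared length over 0–3,000 Mbp from the reference counts; totals above
  3,000 clamp into the last bin and queries into an empty bin consult the
  nearest populated bin (ties toward the lower bin).
* **IBD0 proportion.** (genome − total)/genome, where the genome length
  is the panel-covered span (sum over chromosomes of last − first SNP
  position, ~2,864 Mbp for the default panel) — detected segments cannot
  extend beyond panel coverage, so a full-genome constant would bias every
  proportion upward. The proportion is matched against the analytic table:
  expected 1 − 2^(1−d), class bounds at 1 − 2^−((2d−1)/2) (upper bound
  inclusive; parent–child ≤ 0.1 and siblings (0.1, 0.365] special-cased;
  unrelated above 1 − 2^−(17/2)).
* **Kinship coefficient.** The robust estimator
  φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(2·N_Aa(i)) + 1/2 − (N_Aa(i)+N_Aa(j))/(4·N_Aa(i)),
  classified by the analytic intervals (2^−((2d+3)/2), 2^−((2d+1)/2)];
  unrelated at or below 2^−(21/2); estimates above the degree-1 bound are
  clamped to degree 1. The classifier defaults to the original robust
  designation of i — the sample with **fewer** heterozygous loci. The
  designation matters at this panel size: with ~10⁴ markers the estimator
  noise is σ ≈ 0.01, and the designation adds a bias of
  ±E|ΔN_Aa|/(4N_Aa) ≈ ∓0.003; the "greater" variant inflates unrelated
  pairs' φ̂ enough to push ~16% of them past the most distant inference
  bound, while the original keeps that at ~5%. The "greater" variant
  remains available as an argument. Degree only — parent–child and
  siblings are not separated by this method.

PCA and PCoA pair embeddings (rows = pairings, columns = per-SNP shared
allele counts; PCoA distances are counts of differing entries over
pairwise-complete columns) are exploratory; no classifier is built on
them.

## Evaluation

An inference is correct when its degree ordinal equals the truth;
relationships within a degree are interchangeable. The unrelated-collapse
rule relabels inferences of degree ≥ 6 as unrelated before scoring, which
stabilises the unrelated class whose members otherwise scatter over
degrees 5–9.

The ROC construction sweeps an error margin t = 0…5: TPR(t) is the
fraction of related pairs inferred within t degrees of truth, FPR(t) the
fraction of unrelated pairs inferred closer than t degrees from the
unrelated ordinal. Points are closed with (0,0) and (1,1) and integrated
by trapezoid. Because the unrelated ordinal sits at one end of the degree
scale this construction is asymmetric: a uniformly random classifier
scores ≈ 0.449, slightly below ½, which is its chance level (computed in
closed form in the test suite). AUROC values from this construction are
therefore comparable across methods but not against ROC curves built from
other response/predictor conventions.

## Problem sizes and determinism

The study configuration used by the acceptance script and the at-scale
tests is the full published design: 18 related types + unrelated, 100
pairs per type split 50 reference / 50 test, a 10,030-SNP panel, 10⁻³
noise; the zero-IBD limit uses 2,000 gene-dropped fourth-cousin pairs.
One such study runs in about a minute on one core. All randomness flows
from a single integer seed through `numpy.random.SeedSequence` spawns, so
every artefact is bit-reproducible given (configuration, seed).

## Known limitations

* Linkage equilibrium founders understate background IBS relative to real
  cohorts; real-data accuracy, especially the separation of unrelated
  pairs from degrees ≥ 6, will be somewhat worse than the synthetic
  floors.
* No crossover interference; realised-kinship spreads are a few percent
  wider than an interference-aware simulator would give, costing a few
  accuracy points at degree 4+. In particular, the kinship-coefficient
  method's fourth-degree accuracy is variance-limited at this panel size
  (realised SD ≈ 0.009 plus estimator SD ≈ 0.01 against an inference
  interval of halfwidth ≈ 0.011) and sits near 55–60% here.
* The 18-type catalogue matches the intended degree span but the exact
  published composition per degree is not fixed by the sources; types
  within a degree differ slightly in realised-kinship variance.
* X/Y markers, multi-allelic records, population structure and
  consanguinity are out of scope.
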