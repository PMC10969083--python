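# Methods

This note records the model implemented by `gfabric`, the conventions and
numerical choices that were genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## Data model

The unit of analysis is a spot-level expression table: microarray spots
(each mapping to exactly one gene; a gene may be probed by 1–3 redundant
spots) × biological replicates × two conditions, reference "N" and
experimental "L". Values are linear, median-normalized intensities.
Rows with any missing or non-positive value in either condition are
dropped at read time and counted; a gene loses only the offending spot,
not its other spots. Genes are matched to gene-set (GMT) files by exact,
case-sensitive symbol; set members absent from the dataset are reported
as a warning and excluded from all denominators that refer to
"quantified" genes. Replicate columns are bound to conditions by an
explicit design map, never by column order. The reference design has
four biological replicates per condition; the code tolerates unequal
counts.

## Primary characteristics

**AVE** is the plain mean over all replicate values of all spots probing
the gene.

**REV** (%) is a bias-corrected coefficient of variation. The replicate
variance is pooled *within* spots — the mean of the per-spot replicate
variances, ν = s·(n−1) degrees of freedom — so a constant intensity
offset between redundant spots (a probe-affinity artifact) does not
inflate the variability estimate. The chi-square mid-interval correction

    c(ν) = ½·(√(ν/χ²₀.₉₇₅,ν) + √(ν/χ²₀.₀₂₅,ν))

averages the two 95% confidence bounds of the standard deviation and
compensates the small-sample underestimation of the CV (c ≈ 2.15 at
ν = 3, → 1 as ν grows). It is on by default and exposed as a config
flag (`cv_correction`) for sensitivity analysis.

**COR** is the Pearson correlation of two genes' values, pairing spot k
of one gene with spot k of the other (file order) for k up to the
smaller spot count s_min, concatenated across replicates — n·s_min
paired values. min() is the conservative generalization to unequal spot
counts. Significance uses the exact two-tailed critical value
r_c = t_c/√(t_c² + df), df = n·s_min − 2; at n = 4 this gives 0.9500,
0.7067, 0.5760 for 1, 2, 3 spots. The published convention prints the
single-spot value as 0.951; we implement the computed 0.950 and provide
`single_spot_cutoff_override` for strict replication of the published
classification. Pairs are classified synergistic (COR ≥ r_c),
antagonistic (COR ≤ −r_c), independent (|COR| < 0.05, a literal
threshold, not an equivalence test) or unclassified. No multiple-testing
correction is applied anywhere: the framework's convention is per-pair
α = 0.05.

## Derived characteristics

**REC** = (transcriptome-median REV)/(gene REV), a pure ratio — the
median gene scores 1, tightly controlled genes score high. The ratio
form (rather than ratio − 1) is consistent with published pathway means
near 1–2 and strictly positive per-gene values.

**COORD** (%) = 100·(n_syn + n_ant − n_ind)/(N−1) over a gene's N−1
partners: both significant synergisms and antagonisms witness
coordination, significant independences count against it, and
unclassified partners contribute only to the denominator.

**GCH** = REC·exp(k·⟨COR²⟩) with the mean over all squared partner
correlations and k = 4 by default (configurable), following the
genomic-fabric literature convention of amplifying expression control by
coordination power. Gene ranking by GCH is invariant to rescaling all
REVs (REC is median-normalized).

Pathway averages of any per-gene quantity are arithmetic means over the
set's *quantified* members, reported with their coverage fraction
(quantified/assigned).

## Regulation between conditions

The signed expression ratio is x = AVE_L/AVE_N when AVE_L ≥ AVE_N, else
−AVE_N/AVE_L (|x| ≥ 1 always). The p-value is the two-tailed Welch
(heteroscedastic) t-test on per-replicate spot-averaged gene values,
because biological replicas — not spots — are the sampling unit. The
per-gene fold-change threshold is

    CUT = 1 + √2·√(REV_N² + REV_L²)/100 ,

the form that reproduces the published (REV_N, REV_L, CUT) triples
exactly (1.09/13.96 → 1.198; 101.47/26.41 → 2.48). A gene is called up
(down) when x ≥ CUT (x ≤ −CUT) and p < α. The comparison helper
additionally categorizes every gene against the uniform 1.5× rule into
falsely-up/-down (uniform hit, CUT miss) and missed-up/-down (CUT hit,
uniform miss).

WIR = AVE_N·(|x| − 1)·sign(x)·(1 − p) applies to every gene regardless
of its call, using the *reference*-condition AVE and the uncapped Welch
p; WPR = √(mean WIR²) over a pathway's quantified members.
ΔREC = (REC_L − REC_N)·100 and ΔCOORD = COORD_L − COORD_N. The
pathway-level control change is 100·(mean REC_L/mean REC_N − 1) over
quantified members; the aggregation at pathway level admits several
conventions and this one is explicit and configurable in the sense that
the per-gene RECs are exported alongside it.

## Pathway coupling and remodeling

Within a set of G quantified genes, the S/A/I counts run over the
G(G−1)/2 distinct member pairs while the coordination-degree denominator
is the **ordered**-pair total G(G−1); between two sets it is
|A|·|B| − |A∩B| (shared genes contribute no self-pair). This
denominator convention is the one under which every published intra- and
inter-pathway percentage reproduces exactly; note it halves naive
distinct-pair fractions, so COORD values from different tools are not
directly comparable without checking the denominator. The remodeling
ratio between conditions is the larger coordination degree over the
smaller, negative when coupling decreased; it is undefined (and reported
as such) when either side is 0. Networks are exported as SIF edge lists
(significant pairs only, optionally including independences) with a node
table carrying the regulation call.

Full-transcriptome pair computation is quadratic (1.9×10⁸ pairs at
N ≈ 19,600) and therefore opt-in; the default scope is pairs
within/between the configured gene sets plus named anchor genes, which
covers every pathway-level statistic.

## Synthetic data generator

The generator emulates the reference study design: two conditions × 4
biological replicates, 1–3 spots per gene (uniform by default),
log-normal baseline AVEs (ln-scale μ = 0, σ = 2: median 1 after
median-normalization, upper tail ~10³ like the top myofilament genes),
per-gene true CVs log-uniform on 1–100%, disjoint correlation blocks,
and a designated map of true fold-changes. Per replicate and condition,
block b draws one latent factor f ~ N(0,1) and gene i takes
AVE·(1 + CV·(ℓᵢf + √(1−ℓᵢ²)ε)) with loading ℓᵢ = ±√ρ (sign pattern
makes members antagonistic); spots add independent noise with sd = 20%
of the replicate-level sd, enough to exercise the pooled-variance path
without dominating; values are clipped at 10⁻⁶ of the median baseline
(negligible for CV ≤ 33%). All randomness flows from one seed through
`numpy.random.default_rng`; regeneration is bit-identical.

The multiplicative noise matches REV's CV semantics but is Gaussian, not
the heavier-tailed intensity noise of real arrays; blocks are an
idealization of pathway co-regulation (uniform ρ, disjoint membership);
and no normalization artifacts, batch effects or probe cross-
hybridization are simulated. Passing recovery tests therefore establish
the *statistical correctness* of the estimators and decision rules under
the declared model, not robustness to real-array artifacts.

Ground truth supports closed-form expectations: the analytic REV is
100·CV·c(ν), the analytic CUT follows from it, and expected pair classes
follow from block membership and sign pattern. Under the study
conditions the suite verifies ≥95% recall of 4×-regulated genes at
CV 10% (n = 4, 500 genes), a false-call rate ≤ α + 2% under the null
(2000 genes), and ≥70% synergism recall at ρ = 0.995 over 200 pairs
(the single-spot fraction of pairs sits near the r_c = 0.95 detection
boundary at n = 4 — Fisher-z se = 1 — while 2–3-spot pairs are recalled
almost surely, so the mixture clears 70%).

## Numerical choices and degenerate inputs

Zero-variance correlation vectors yield an undefined COR, recorded as
missing and classified unclassified. A zero REV (constant replicates)
makes REC infinite; it is reported with a warning rather than silently
capped. Welch's test returns p = 1 for identical zero-variance groups.
Problem sizes in the test suite (≤2000 genes, ≤500 pairs per property)
were chosen so each statistic's sampling error is well below the margin
it is tested against while the whole suite stays interactive.

## Known limitations

* Spot pairing for multi-spot correlations assumes file order is
  meaningful (probe sets are listed consistently across genes on a
  platform); an arbitrary permutation of one gene's spots can change its
  multi-spot CORs.
* REC/GCH depend on the transcriptome-median REV, so restricting the
  analysis to a small gene subset changes their scale; the pipeline
  computes the median over all quantified genes in the run scope.
* The exported coordination degrees use the ordered-pair denominator
  described above; divide by 2 only with care when comparing to tools
  that use distinct-pair fractions.
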