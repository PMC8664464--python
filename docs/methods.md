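# Methods

## Landmark scheme and data model

Heads carry 16 named 2-D landmarks: the median ocellus and mandible center
on the facial midline, plus seven anatomical left/right pairs (lateral
ocelli; eye tops, bottoms and maximum arcs; cheek arcs; the endpoints of the
maximum interocular distance; the antennal sockets). Side identity is fixed
by label, never inferred from coordinates — inference would fail exactly on
the deformed hybrid heads the package exists to analyze. TPS input assumes
mathematical y-up coordinates; image-origin files need `flip_y=True`, an
explicit flag because a silent mirror flip would corrupt every left/right
result downstream.

Digitizing replicates (protocol: three per head) are averaged landmark-wise;
any replicate count ≥ 1 is accepted with a warning below three.

## Linear measures and ratios

MIO and AIO are inter-landmark distances; FE (eye bottom to mandible
center) and FEP (perpendicular offset of the cheek arc from the FE line)
are computed per side and averaged for ratio reporting, with per-side
values retained for asymmetry work. MHW and HL endpoints are head-outline
extremes that are not among the 16 landmarks; they must be supplied as
auxiliary points or via the measurement CSV. OIO is ambiguous at the
landmark level: by default the lateral-ocellus separation is used and
flagged `oio_is_proxy`; explicit eye-margin endpoints can be passed as aux
points instead. All ratios are exact quotients, so they inherit the
similarity invariance of the underlying distances.

## Procrustes superimposition

The pairwise fit centers both configurations, optionally rescales each to
unit centroid size, and rotates by the closed-form least-squares optimal 2-D
rotation θ* = atan2(Q, P) with P = Σ aᵢ·bᵢ and Q = Σ (a_y b_x − a_x b_y).
Only proper rotations are considered; reflection is never applied
implicitly. In scale mode the reported residual additionally includes the
least-squares size factor β = r (full Procrustes), giving the residual
1 − r² between unit-size shapes; the aligned coordinates themselves are
kept at unit centroid size. Without scaling the residual is the plain sum
of squared landmark distances, which is symmetric in the two shapes.

GPA iterates rotation-to-consensus and consensus re-estimation (coordinate
mean, renormalized to unit centroid size) until the consensus moves less
than 1e-8 (root summed squared change) or 100 iterations; both constants
are arguments. Scaling to unit centroid size is the default, matching
standard geometric-morphometrics practice; a no-scale mode exists for
sensitivity checks since the original protocol does not state which was
used.

## Object-symmetry scoring

A head is compared with its mirror image: the configuration is rotated so
the axis through the two midline landmarks is vertical, x is negated about
that axis, the rotation is undone, and each left label is swapped with its
right partner (an exact isometric involution; centroid size is preserved to
the bit). Any residual misalignment of the mirror axis is absorbed by the
subsequent Procrustes fit, so the choice of mirror line does not affect the
score. D_sym is the full-Procrustes residual between the head and its
reflection; because both copies are at unit centroid size, D_sym is already
normalized by total landmark variance and the percent score is
100·√(1 − D_sym) — the PROTEST correlation statistic. The percent formula
is an adopted interpretation (the source analyses report percent
correlations without a formula); raw D_sym is always reported alongside.
Residuals below 1e-12 are snapped to zero so that exactly symmetric
configurations score exactly 0 / 100%.

Group contrasts use Welch (unequal-variance) t-tests on per-specimen D_sym;
"t-test" was otherwise unspecified. With two zero-variance samples the
degenerate rule is p → 0 for differing means and (t, p) = (0, 1) for equal
ones. Appendage asymmetry is one-way ANOVA on |left − right| (magnitude of
asymmetry; signed differences are available via a flag); all-identical
differences report F = 0, p = 1 rather than NaN.

## Statistics

Mann–Whitney U reports min(U_x, U_y). Exact p (doubled one-tail, capped at
1) is used when n·m ≤ 400 with no ties, otherwise the tie-corrected normal
approximation with continuity correction; both are delegated to
scipy.stats.mannwhitneyu, and the exact branch is verified against an
exhaustive enumeration oracle over every size pair with n·m ≤ 100.
Bonferroni adjustment is min(1, m·p) over a caller-assembled family —
family boundaries are configuration, because the protocol names the
comparisons but not the family arithmetic. Chi-square homogeneity is
Pearson's statistic without Yates correction; expected cells below 1 set a
warning note.

## Cross simulator

The three clefting loci sit on different chromosomes and are modeled as
unlinked markers with independent ½:½ segregation in haploid F2 males;
intra-chromosomal recombination and map distances are not modeled. The rule
set gives p_base = 0.25 to three genotype classes (Chr 5 Nv with an Ng
allele at Chr 2 and/or Chr 4; Chr 5 Ng with Chr 2 and Chr 4 both Nv; all
three Nv) and 0 otherwise; Nl alleles act Ng-like, which makes clefting
impossible in Nl×Ng F2 males, as observed. The uniform mixture over the 8
patterns gives the closed-form F2 cleft fraction 5/32 = 0.15625. The rate
for the "Chr 5 Ng, others Nv" cell is not separately reported; it defaults
to p_base and is configurable.

Recessivity: a diploid heterozygous at any rule locus has probability 0 —
this realizes "the interactions are recessive" and reproduces the normal
phenotypes of F1 diploid males and F1 hybrid females. (Masking heterozygous
loci as Nv-like instead would wrongly trigger the all-Nv background rule on
F1 males.) The all-Nv rule is treated as an F2 hybrid-background effect and
fires only there; pure-species genotypes never cleft. The 2C-Cli
introgression line overrides to probability 1.0 (completely penetrant in
both sexes); wm114 carries only the *dsx* regulatory region and does not
cleft.

Empirical-mode cohorts are single multinomial draws from per-cross
defect-class tables. The defaults are calibration constants assembled from
the printed per-cross frequencies: total defect rates 88% (Ng×Nv), 80%
(Nl×Nv), 20% (Nl×Ng); the Nl×Ng breakdown (no clefts, 5% each asymmetry
class, 10% miscellaneous = half of all defects, no multiples) is printed
outright, while the within-cross splits for the crosses to Nv are chosen
inside the printed ranges (asymmetries ~24–34% each, multiples 10–12%,
miscellaneous ~20%). "Multi" is its own multinomial class, as tabulated —
joint modeling would need co-occurrence data that does not exist. These
tables are generator parameters, not predictions.

Dominance of head-shape ratios in diploid F1 males is a per-ratio weight w
toward the Nv mean (trait mean = w·Nv + (1−w)·Ng): OIO/HL Nv-dominant
(w = 1), AIO/HL and MHW/HL Ng-dominant (w = 0), MIO/HL and FEP/FE additive
(w = 0.5), following the observed indistinguishability pattern.

## Synthetic data generator

Templates are fictional but dimensioned (head length ≈ 1) and constrained
so the noiseless ratio orderings match the wild-type comparisons: Nv males
widest (MHW/HL), Ng males narrowest-faced (OIO/MIO/AIO over HL below both
Ng females and Nv males) with the largest cheeks (FEP/FE), Nl males
intermediate for MIO/HL and FEP/FE, and the subtler female orderings (Nv
females widest-headed, smallest-cheeked). The F2 hybrid template is the
Nv♂/Ng♂ midpoint.

Noise is deliberately factored into three channels so asymmetry is
attributable by construction: a mirror-symmetric among-individual field
(SD 0.010; paired landmarks receive mirrored copies of one draw, midline
landmarks move only along y), per-side fluctuating asymmetry (independent
isotropic Gaussian per landmark), and digitizing noise per replicate
(SD 0.002, three replicates averaged). Defect morphs displace specific
landmarks: cleft pulls the mandible center up and pinches the antennal
sockets (symmetric), lateral asymmetry pushes one cheek/eye arc outward,
DV asymmetry shears one eye's top/bottom, miscellaneous raises the ocellar
field ("swollen head"); multi = cleft + lateral.

The two FA defaults are frozen calibration constants, fitted once by
numeric search (n = 3000 heads per candidate value) so the default
wild-type and hybrid cohorts score ≈ 99.5% and ≈ 93% mean correlation
under the adopted symmetry statistic, then never revisited: wild-type
FA SD = 0.0215, hybrid FA SD = 0.082 (template units). The calibration
depends on the adopted percent-correlation definition; the reported scale,
not the formula, is the anchor. Appendage lengths (T1 leg mean 1.2,
forewing mean 1.5, individual SD 0.04, side SD 0.006 — side noise identical
across groups, hybrids included) reproduce the finding that hybrid
asymmetry is head-specific.

What a green test establishes: that the pipeline recovers the statistical
structure the generator put in (orderings, penetrances, calibrated
symmetry scale). It does not establish anything about real specimen images,
absolute sizes, pixel scales, correlated digitizing error, or
non-Gaussian FA — none of which the generator emulates.

## Numerical choices and limitations

* Rotation optimum is closed-form; brute-force 0.001-radian grids serve as
  test oracles only.
* Symmetry residuals < 1e-12 snap to 0; correlation is clamped to [0, 100].
* GPA: tol 1e-8, cap 100 iterations, configurable.
* Cohort sizes mirror the study design (58 wild-type and 105 hybrid heads,
  72 wild-type appendage specimens); head and appendage cohorts are
  independently specified, as in the source counts.
* No thin-plate splines, shape PCA, directional-asymmetry decomposition,
  QTL mapping, or image processing — out of scope by design.
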