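# Methods

This note documents the models, conventions, and design choices behind
`dualeigen`, in the order the pipeline runs them.

## Spatial chip normalization (sub-sub)

**Model.** Probe-level spatial artifacts (uneven hybridization, washing)
are smooth on the scale of tens of probes, so a target chip is adjusted
against a reference chip *locally*. The grid is partitioned into square
subarrays of `subarray_size` (default 50) overlapping by `overlap`
(default 25) per axis; regular window starts step every
`size − overlap` cells, and if the final regular window misses the grid
edge one extra window anchored at `length − size` is appended (a 1002-cell
axis yields starts 0, 25, …, 950, 952 — 40 per axis, 1600 windows).
A consequence of this edge policy is that cells near the edge-anchored
windows can lie in up to 3 windows per axis, i.e. up to 9 in 2-D
(4 away from the edges); the average over all covering windows is taken
per probe.

**Within-window fit.** The reference intensity is regressed on the target
intensity (both log2; raw TSV intensities are floored at 1.0 before the
log) with a continuous one-knot piecewise-linear model
f(x) = b₀ + b₁x + b₂(x−κ)₊, fitted by least trimmed squares: minimize the
sum of the h = ⌈0.75·n⌉ smallest squared residuals. Knot candidates are
the interior deciles of the window's target intensities and are scanned
exhaustively. For small windows (C(n, h) ≤ 20 000) the LTS optimum is
found by exhaustive best-h-subset search; otherwise by seeded
concentration steps (FAST-LTS style) from a deterministic start plus a
fixed number of random restarts, so the fit is reproducible for a given
input and configuration.

Two degeneracies need explicit handling. (i) If the trimmed subset has
fewer than 3 points strictly on one side of the knot, that segment is
unconstrained by the criterion (any slope gives the same trimmed RSS); the
fit then collapses to a single line on the subset. (ii) An all-constant
target window falls back to a location-only LTS fit, flagged. A window
where target and reference agree elementwise is the identity map by
construction, which makes self-normalization (`subsub_normalize(X, X)`)
return X exactly, not merely to rounding. A constant offset is absorbed
exactly wherever windows are homogeneous; windows straddling the boundary
of a shifted region see two inconsistent relations at interleaved
intensities and can only fit the majority, so a regional artifact shrinks
rather than vanishes there.

## Probe-set summarization (probe + chip model with references)

Per probe set (11 probes typical), log2 intensities across *all* chips —
including designated reference chips — are fitted with the additive model
I(p, j) = μ + αₚ + βⱼ by Tukey median polish, with row and column effects
median-constrained to zero. The reported expression of the probe set on
chip j is μ + βⱼ; reference chips anchor the fit but are excluded from
the output profile. Because probe effects are constrained by a median,
only between-chip *differences* are identifiable — which is exactly what
downstream centering consumes. Probe sets with fewer than 2 probes fall
back to the per-chip mean and are flagged. Median polish was chosen as
the robust additive fit: a probe biased by a constant on all chips moves
αₚ only, and a single corrupted (probe, chip) cell is damped well below
its 1/11 share of a naive mean.

## SVD conventions

The decomposition runs on the gene-centered matrix by default
(configurable: none / gene / sample / double, recorded in the output
metadata). Gene centering was chosen because a leading component of an
uncentered log-intensity matrix is dominated by the grand mean, which is
incompatible with leading components explaining only ~11–16% of a real
spectrum; the published cumulative percentages also pin down the
contribution convention as **linear in ρ** — 100·Σ_{k≤K}ρₖ/Σₖρₖ
reproduces every published cumulative cell from the printed values and
the rank-1 percentage, while the ρ² convention does not (e.g. it would
give 25.18% where 27.17% is printed). The convention is scale invariant.

Sign anchoring: each sample eigenvector is flipped (together with its
gene eigenvector) so its Spearman correlation with a designated attribute
(default `week`; diet is encoded as an HFD indicator) is nonnegative;
exactly zero or undefined correlation anchors by making the
largest-magnitude loading positive, flagged. Tolerances: orthonormality
1e-8, relative reconstruction 1e-6 — ordinary double-precision headroom
for LAPACK's deterministic SVD.

## Dual comparison and classification

Only gene eigenvectors are compared across the pooled and control-only
decompositions (the sample sets differ). Matching is greedy on the
top-k × top-k |cosine| matrix (k ≤ 5 is ever inspected; greedy equals
optimal assignment on well-separated spectra and is simpler to audit);
pairs below `min_similarity` (default 0.3) stay unmatched. Classification:
matched with |cos| ≥ `sim_threshold` (default 0.6) → endogenous; unmatched
*and* diet-associated (Bonferroni over the factors tested per component,
α = 0.05) → exogenous-candidate; anything else — including matched but
dissimilar components — unclassified. Requiring "no match at all" for the
exogenous label keeps classification monotone in the threshold: raising
it can only demote endogenous to unclassified, never flip it to
exogenous-candidate.

Factor associations: binary factors (diet, week-18 subgroup) use the
two-sided Wilcoxon rank-sum, exact when both groups have ≤ 12 samples and
no ties, else the tie- and continuity-corrected normal approximation;
ordinal/continuous factors (week, GTT/ITT AUC) use Spearman correlation
with the t-approximation p-value, restricted to samples with measured
values. Note Spearman reaches ±1 only when the factor itself is untied.
A constant loading vector returns p = 1, flagged degenerate.

## Wilcoxon rank-scoring of gene sets

Genes are ranked ascending with midranks; a set's statistic is the
rank-sum of its members, and the one-sided p per end is the tail
probability over all C(g, m) equally likely member placements. Midranks
make the two-end duality exact: reversing the sort maps ranks r to
g+1−r, whose multiset is unchanged, so p_low on u equals p_high on −u to
machine precision. The exact null is computed by a counting recursion on
doubled (hence integer) ranks when m ≤ 10 and g ≤ 1000 — thresholds
chosen for desk-scale runtime, configurable — and matches brute-force
enumeration; larger instances use the tie- and continuity-corrected
normal approximation, which is calibrated to within ±0.01 at the 0.05
level in the regimes the pipeline uses. Bonferroni multiplies the better
end's p by the number of sets scored, capped at 1; only Bonferroni is
offered. The scorer accepts any per-gene statistic (group mean
differences as well as eigenvector loadings) since it depends on ranks
only.

## Motif association

The JASPAR 4-row count matrix is normalized per column after adding
`pseudocount × background` (default 0.01, uniform background); scores are
log2 odds against the background, floored at −30 bits for
zero-probability cells. A promoter's best window score over both strands
(N scores as background, i.e. contributes 0) is converted to a per-window
significance using the *exact* distribution of the window score under the
i.i.d. background model, computed by convolving per-column score
distributions on a 0.001-bit grid; significances are combined over the L
scanned windows as 1−(1−p)ᴸ and transformed to a binding strength
−log10(combined), which is monotone decreasing in the combined
significance and strand-symmetric by construction. Sequences shorter than
the motif get strength 0, flagged.

The association statistic is deliberately transparent: with affinities w
ordered by the sorted gene statistic and centered by the universe mean,
R(i) = Σ_{j≤i}(wⱼ−w̄); the score is maxᵢ|R(i)| with the extremum position
recording the end (head/tail). Significance is the add-one permutation
p-value over uniform shuffles of the affinity profile (default
n_perm = 999, seeded), which is valid by construction:
P(p ≤ α) ≤ α + 1/(n_perm+1) under the null. This running-sum maximum is a
variant of binding-association enrichment scores; no attempt is made to
reproduce any specific external tool's transform, and the scanner
replaces an external motif-search dependency with the analytic null
described above.

## Synthetic data: what it emulates, and what it does not

The generator mirrors a two-diet × three-week × three-replicate design
(18 samples). The endogenous sample loading is the centered week vector
(monotone in age); the exogenous loading starts from a week-scaled HFD
indicator and is Gram-Schmidt-orthogonalized against the endogenous
loading *restricted to the HFD support*, which keeps control entries
exactly zero — in the balanced design this collapses to a pure HFD
indicator, giving clean diet separation in the pooled decomposition and
exact disappearance from the control-only one. Gene eigenvectors are a
random orthonormal pair. `endo_strength` and `exo_strength` (defaults 8
and 5) are per-gene RMS amplitudes: a component contributes
strength·√n_genes to the singular spectrum, so at the default unit noise
both planted components sit far above the random-matrix detection
threshold, as strong tissue programs do; the published study reports no
effect sizes, so these defaults are chosen once for testability. The
matrix carries no per-gene baseline, so noise-free output has numerical
rank equal to the number of planted components; real log-expression
baselines are rank-1 structure that gene centering removes anyway.

Not emulated: probe-sequence affinity effects, count-based (RNA-seq)
noise, batch structure, and correlated gene-gene noise. Passing the
planted-recovery tests therefore demonstrates that the algorithms do what
they claim under their own assumptions (i.i.d. Gaussian noise on the log
scale, orthogonal planted components), not that any particular real
dataset has this structure.

Tolerance-test attributes (GTT/ITT AUC) are simulated only at the
terminal week with an HFD upward shift, and the HFD terminal group is
median-split into worse/better subgroups, mirroring how such phenotypes
enter the association stage.

## Problem sizes and numerical choices

Simulated studies use 2000 genes × 18 samples; planted-recovery claims
are evaluated over 20 seeds; permutation nulls use 999 shuffles; the
Wilcoxon calibration uses 2000–5000 replicates; full-size chip checks use
the 1002×1002 geometry and smaller grids (100–200) elsewhere. These sizes
make the whole suite run in minutes on a single CPU while keeping every
statistical check adequately powered. All randomness flows from explicit
seeds; reruns are byte-identical, including every table the pipeline
writes (`%.10g` float formatting, fixed orderings).

## Known limitations

- The probe/treatment/reference summarization is implemented as the
  median-polish additive model described above; other robust additive
  fits would differ in detail.
- LTS via concentration steps is a heuristic for large windows; it is
  exact (exhaustive) only for small n, and pathological windows could in
  principle settle in a local optimum.
- Greedy component matching can differ from optimal assignment when the
  similarity matrix has near-ties across components.
- Reproducing a specific published spectrum from raw public arrays
  requires the original reference-chip selection and centering choices,
  which are not part of this package; real data enters through the
  expression/attribute TSV loaders.
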