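# Methods

## Model

A pedigree of n individuals, sorted so parents precede offspring, implies
the additive (numerator) relationship matrix **A** of the standard
quantitative-genetic model: founders are draws from a non-inbred, unrelated
base population; every other individual's genetic value is the parent
average plus a Mendelian sampling deviation with variance d_i, where

* d_i = 1 with both parents unknown,
* d_i = 0.75 − 0.25·F_p with one known parent p,
* d_i = 0.5 − 0.25·(F_s + F_d) with both parents known,

and F is the inbreeding coefficient (half the additive relationship of the
parents; `diag(A) = 1 + F`). Unknown parents contribute nothing — there are
no unknown-parent groups or metafounders. In this model `A = L·Lᵀ` and the
inverse factor `L⁻¹` is assembled row by row directly from the pedigree:
row i holds `1/√d_i` on the diagonal and `−0.5/√d_i` under each known
parent, so `nnz = n + 2p + q` for p individuals with both and q with one
known parent (≤ 3n). Note the count assumes sire ≠ dam; a selfing row would
merge its two parent entries into one of twice the weight, which is the
correct algebra but a different count.

All linear algebra is matrix-free. `A·x` is a backward substitution with
`(L⁻¹)ᵀ` followed by a forward substitution with `L⁻¹`; both are performed
through one SuperLU factorisation of the triangular `L⁻¹` with natural
ordering and no pivoting, reused for both solve directions (exact direct
solves, no iterative refinement — the factor is triangular with unit-scale
entries and benign conditioning). The centred matrix `Ã = Pₙ A Pₙ` with
`Pₙ = I − 11ᵀ/n` is the pedigree expectation of the genomic relationship
matrix; its product needs only a mean subtraction before and after the two
solves. `Ã` annihilates constant vectors exactly, so centred score columns
sum to zero.

## Inbreeding

F is computed with the Meuwissen–Luo ancestor-tracing algorithm: for each
individual the ancestor set is gathered, processed in decreasing index
order accumulating the corresponding row of **L**, and
`F_i = −1 + Σ_j L_ij² d_j`. A sentinel F = −1 for unknown parents folds the
one-/no-parent Mendelian variance cases into the two-parent formula. The
kernel is numba-compiled; cost is proportional to the summed ancestor-set
sizes (linear in n for shallow pedigrees, which is what makes the
million-record runs cheap), and no dense matrix is ever formed.

## PCA

Both backends return the covariance-of-individuals convention: for
`A = W·diag(λ)·Wᵀ`, scores are `W·diag(λ)` and the reported per-component
standard deviation ("sdev") is `√λ` — the singular value d of **L**, not
divided by √(n−1). Variance proportions are `d²/Tr`, which sum to one at
full rank.

**Randomised SVD** (default): draw a Gaussian test matrix Ω (n×l), form
`Y = op·Ω` in one pass, orthonormalise by QR into the range basis Q, and
refine with `power_iterations` further passes `Q ← orth(op·Q)` (default 1;
each pass is re-orthonormalised, which keeps slowly decaying spectra
accurate at modest cost). Then `Z = Lᵀ·(PₙQ or Q)` is obtained by one more
backward substitution; the thin SVD `Z = W·diag(d)·Vᵀ` gives sdev = d and
scores `Q·V·diag(d²)` truncated to k. Defaults k = 10, l = 15; when only k
is given, `l = max(15, ⌈1.5k⌉)` soft-capped at 2k (a warning, not an error,
beyond that — larger sketches buy little). The test matrix is generated
column-major from a seeded generator, so results are reproducible
bit-for-bit for a given seed. At l = n the sketch is exact and the
decomposition equals the dense one; within (near-)degenerate eigenvalue
clusters individual columns are only defined up to rotation, so exactness
tests compare sdev per component and scores through basis-free Gram
matrices.

**Lanczos**: `scipy.sparse.linalg.eigsh` (ARPACK) driven by the same
implicit operator with a seeded start vector, eigenvalues clipped at zero,
same score convention, so the two backends agree to solver tolerance.

Component signs are indeterminate; `align_signs` flips each score column so
its largest-magnitude entry is positive, making outputs comparable across
runs and platforms. Near-equal eigenvalues are ordered by descending sdev.

## Total variance

Truncated decompositions cannot recover the trace, so it is supplied
separately: `Tr(A) = n + ΣF` exactly, and
`Tr(Ã) = Tr(A) − (1/n)·1ᵀA1` with one uncentred product. When only `L⁻¹`
is available, the Hutch++ estimator is used: the budget b is split into
thirds m = b//3 (rounding down, reported back as 3m); a Rademacher sketch S
gives Q = orth(A·S); the estimate is `Tr(QᵀAQ)` plus Hutchinson probing of
the residual `(I−QQᵀ)A(I−QQᵀ)` with m fresh Rademacher vectors. Rademacher
probes are used for both stages (variance-optimal for Hutchinson-type
estimators). The estimator is unbiased, and the PSD structure of A makes
the residual small: the default budget of 120 products typically gives
well under 1% relative error, and plain Hutchinson (kept internal, for
tests only) is markedly noisier at equal cost. The exact path is always
preferred when the pedigree, hence F, is available.

## Pedigree handling

Input is delimited text (comma or tab auto-detected, header optional,
unknown parents coded 0/NA/empty/.). Cleaning operations mirror what large
registry pedigrees need: insertion of founder records for parents never
listed as individuals; stable topological sorting (Kahn's algorithm,
input-order tie-break, permutation back to input order retained) with loop
detection that names an individual found to be its own ancestor — severing
the offending sire link is an explicit CLI flag (`--fix-loops`), never
automatic; and forward generation counting (founders are generation 1,
everyone else one more than their highest-generation known parent; for a
"founder" appearing mid-pedigree this max-parent rule is a convention, as
no standard exists). `L⁻¹` interchange uses 1-based MatrixMarket
coordinate format, lower triangle only.

## Scenario generators

The generators exist to validate pedigree PCA against known structure, and
their defaults are the study designs themselves.

**2pop** — two populations of 50 founders; two traits with genetic variance
1.0, genetic correlation −0.3 (1,000 additive QTL, 100 per chromosome,
bivariate Gaussian effects rescaled so founder genetic variance is exactly
1.0 per trait — per-trait rescaling leaves the correlation untouched) and
environmental variance 2.0; 20 generations of truncation selection on
phenotype (top ten of each 50-candidate cohort; trait 1 in population 1,
trait 2 in population 2), 50 offspring per population per generation, sire
and dam drawn uniformly from the selected ten, never equal. At generation
10 a crossbred population is founded as strict population-1 ×
population-2 crosses (five index-selected parents per line) and then
propagated alongside: each later cohort of 50 has two parents from each
pure line and six hybrids, ranked on an equal-weight phenotype index.
Total: 100 + 2×50×20 + 11×50 = 2,650 individuals, a count fixed by the
design, not the seed.

**4pop** — no selection: 200 founders random-mate at constant size for 10
generations; the final generation is split into four disjoint groups of 50
that found four isolated populations, each propagated for nine further
generations (parents only from the own population — no gene flow). All
200 + 2,000 + 1,800 = 4,000 individuals are recorded, including the
ancestral phase.

**Genomes.** Founder haplotypes are Bernoulli draws from
population-specific allele frequencies produced by Wright–Fisher drift
(ancestral frequencies Uniform(0.05, 0.95); drift population 100 diploids;
100 generations of divergence for 2pop; loci fixed everywhere are redrawn
so all 11,000 loci on 10 one-Morgan chromosomes segregate). Genotypes then
descend by gene dropping: per meiosis and chromosome, a random starting
haplotype and Poisson(length)-many crossovers at uniform positions
(Haldane, no interference). With base frequencies p known, the realised
relationship `G = (PₙX)(PₙX)ᵀ / Σ 2p(1−p)` has pedigree expectation
`Pₙ A Pₙ` over founder draws and meiosis — the property the test suite
verifies by replication.

**What the emulation does and does not capture.** The drift emulation
reproduces the divergence level and family structure the designs call for,
but not coalescent linkage disequilibrium or any particular genealogy, and
founders are in linkage equilibrium. Pedigree-side statistics are
therefore faithful to the design (the recorded pedigree depends only on
population sizes, selection and mating rules), while genotype-side numbers
are indicative. Concretely, across ten seeds the 2pop pedigree PCA gives
non-centred PC1/PC2 near 27%/21% and centred PC1/PC2 near 28%/6%, with
the centred PC2–generation correlation ≈ −0.97 and PC3 always ≤ ~3% —
close to the single published run (25/20, 26/5.7, −0.97, <3%). The
generation–PC1 correlation of the non-centred PCA averages ≈ 0.77 (seed sd
≈ 0.10) against 0.88 in the published run: within each pure line the
correlation is ≈ 0.99, and the global value is diluted by seed-dependent
PC1 offsets between the two lines and by the hybrid cohorts' early
saturation, details sensitive to unprinted choices of the original mating
bookkeeping. The 4pop non-centred PC1 share comes out ≈ 4% (published
6.2%), and the centred leading components ≈ 1% each (published ≈ 4–5%),
with the qualitative geometry — a central ancestral cloud with four
well-separated arms — reproduced; recording eleven ancestral cohorts of
200 from a drift founder pool is the main suspected cause of the smaller
shares.

## Problem sizes and tolerances

Dense-oracle comparisons (tabular-method A, eigendecompositions) run on
random pedigrees up to n = 200 at 1e-6 relative (1e-10 for the
`L⁻¹AL⁻ᵀ = I` identity, 1e-9 for traces); scenario statistics average ten
seeded default-size runs; the meiotic-expectation check uses an n = 150
pedigree with 1,500 loci and 125 vs 500 replicates (the max-entry error
should roughly halve when replicates quadruple); the scale check runs a
four-cohort million-record pedigree end-to-end. The acceptance script
re-runs both scenarios over ten seeds in about a minute on one CPU.

## Limitations

* Unknown-parent groups, metafounders and single-step (pedigree +
  genotype) matrices are out of scope.
* The Lanczos backend inherits ARPACK's behaviour on tight eigenvalue
  clusters; the randomised SVD backend is the default and the reference.
* `dense_A_oracle` is a quadratic-memory test oracle, capped at n = 2,000
  by default.
* Triangular solves are sequential; no parallel or out-of-core paths.
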