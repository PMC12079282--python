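# Methods

## The descriptor engine

A molecule is an ordered list of element-labelled points in 3D (angstrom
coordinates) with a total charge. Descriptors are built in four stages.

**Metric.** A pairwise spatial metric over atom coordinates fills an
order-2 matrix; order-3/4 tensors assign each distinct-index atom tuple
the sum of the metric over its internal pairs (3 pairs for triples, 6 for
quartets), which preserves permutation symmetry of the tuple and reduces
to the pair metric at order 2. Tuples with repeated indices are zero.
Metric tokens `M<k>` denote Minkowski distances: `k >= 10` is read as
order k/10 (`M12` → p = 1.2, `M15` → p = 1.5), smaller k as order k
(`M3` → p = 3); `CH` is Chebyshev. A Bhattacharyya slot exists in the
registry but is gated until a formula is registered; no packaged
descriptor needs it. This token grammar is a documented interpretation,
configurable through the registry, not a claim about any external
software's internals.

**Canonical frame.** Minkowski metrics with p ≠ 2 (and Chebyshev) depend
on the coordinate axes, while molecular descriptors must not depend on how
a structure happens to be oriented. The descriptor pipeline therefore
centres each molecule at its centroid and rotates it onto the principal
axes of its coordinate covariance (descending variance) before evaluating
metrics. Axis *signs* are irrelevant because every supported metric is a
function of absolute coordinate differences, so the frame is unique
whenever the principal moments are distinct — generically true for random
and for real catalyst geometries; exactly symmetric tops (degenerate
moments) have an ambiguous frame and are the known exception. Raw
`pair_matrix`/`tuple_tensor` calls operate on coordinates as given; only
the descriptor pipeline canonicalizes.

**Cutoff.** Applied before normalization so stochastic rows renormalize
over the surviving neighbours: `KA` keeps everything; `LGP[k]` zeroes
every entry whose tuple contains a pair more than k bonds apart (bonds are
perceived from covalent radii with a 25% tolerance; lags by breadth-first
search, disconnected pairs infinite); `LGL[a-b]` zeroes entries containing
a pair whose Euclidean distance falls outside [a, b] angstroms. Angular
cutoffs are recognized by the parser and rejected as unimplemented.

**Normalization and power.** `NS` leaves the matrix; `SS` divides each row
(each leading-index slice for tensors) by its sum; `DS` is Sinkhorn
row/column alternation to tolerance 1e-8 (capped at 10,000 alternations;
order 2 only); `MP` divides by the grand sum. A trailing digit is a true
matrix power applied after normalization (`SS3` = row-stochastic matrix
cubed; power 0 = identity), defined for order 2 only. Inside the
descriptor pipeline a row whose entries were all removed by the cutoff is
left at zero rather than raising: aggressive windows legitimately
disconnect atoms, whose LOVI is then 0. Standalone `normalize_matrix`
raises on zero rows unless asked to keep them.

**Maps and aggregation.** With processed array g and per-atom weight
vectors x (and y for bilinear), the local vertex invariants are
L_i = Σ_j g_ij x_j (linear; unit probe on the leading index),
L_i = x_i Σ_j g_ij x_j (quadratic), L_i = x_i Σ_j g_ij y_j (bilinear);
order-3/4 forms extend the sums over the remaining tuple indices with the
same weight applied at every summed position. The LOVI sum equals the full
algebraic form value by construction. Aggregators: S sum, AM mean, GM
geometric mean of absolute values (0 if any LOVI is 0), VC sample
std / |mean| (NaN at zero mean), I50 median, N1/N2 Minkowski norms,
MAX/MIN, V sample variance, RA range. The name-grammar flags `AB` and
`nCi` are parsed and carried in provenance but are semantic no-ops; local
(non-total) scope parses and raises as unimplemented.

## Atomic properties and charges

Ten weighting properties are supported. Nine ship as per-element CSV
tables consolidated from standard compilations: masses (amu), van der
Waals volumes from Bondi/Alvarez radii (Å^3), dipole polarizabilities
(Å^3), Pauling electronegativities, element-level Ghose–Crippen logP
contributions, element-level polar-surface-area contributions (Å^2),
atomic refractivity contributions, Pearson absolute hardness (eV) and
softness stored as exact reciprocals of hardness (eV^-1). These are
element-level approximations — no hybridization- or environment-dependent
atom typing is attempted.

The tenth property, the Gasteiger–Marsili charge, is molecule-dependent:
partial equalization of orbital electronegativity with
χ(q) = a + bq + cq^2, transfers across perceived bonds attenuated by
damping^k at iteration k (defaults: 6 iterations, damping 0.5, the classic
scheme). Transition metals (Ru/Rh/Os/Ir) have no PEOE parameters; by
default they keep their formal charge fixed and are excluded from
transfer (a strict mode raises instead). Any residual between the formal
charges and the declared total charge is seated on the metal, so charge
is conserved exactly.

## Regression and validation

The response is y = log10(r0 / M s^-1) (a sign flag supports the
reciprocal convention; the packaged dataset's training mean of −5.84
against the reference intercept −5.72 fixes +log10 as the default). The
packaged reference model has k = 4 descriptors, so F-statistics use
(4, 20) degrees of freedom at n = 25.

OLS fits go through statsmodels; a fast QR path (asserted equal in tests)
drives the resampling loops. Validation:

* **Q^2_LOO** uses the PRESS identity e_i/(1−h_i), which equals n explicit
  refits exactly and makes genetic-algorithm fitness evaluation cheap.
* **Bootstrap Q^2** pools out-of-bag squared errors over B = 500 case
  resamples against deviations from the full-sample mean. At n = 25 each
  refit sees ~16 distinct rows, so this estimator is deliberately more
  pessimistic than R^2; the gap closes by n = 100.
* **Y-randomization** permutes the response R = 5000 times; because the
  hat matrix is fixed, all refits are vectorized. Under the null,
  E[R^2] = k/(n−1) (= 4/24 = 0.167 at the reference geometry).
* **Diagnostics**: Shapiro–Wilk (scipy's Royston approximation, verified
  against R's shapiro.test), Durbin–Watson with a seeded permutation
  p-value (two-sided around the null centre 2; the exact null depends on
  the design, and permutation is assumption-free), VIF from auxiliary
  regressions.
* **Importance** is the absolute t-statistic |b_j/se_j|, with shares
  normalized to 100% over the descriptors.

**GA selection** evolves fixed-size column subsets with tournament
selection (size 3), uniform crossover at rate 0.5, per-gene mutation at
rate 0.01, and single-individual elitism, fitness = training Q^2_LOO.
Desk-scale defaults are 200 x 100 (population x generations); the
literature-scale 10,000 x 1,000 is reachable by arguments. Duplicate genes
cannot arise (children are sampled without replacement from parent
unions); chromosome fitness is cached.

**Random-split robustness** refits fixed model columns over repeated
random train/test splits and reports medians and IQRs of R^2, Q^2_LOO and
Q^2_EXT (external Q^2 normalizes by deviations of the test response from
the training mean). Degenerate splits are skipped and counted.

## Applicability domain and screening

Williams plot: training leverages from the hat diagonal (their sum is
k+1), query leverages x0'(X'X)^-1 x0 with intercept-augmented rows,
thresholds h* = 3(k+1)/n and |standardized residual| = 3 — the
conventional choices. NCA maximizes the stochastic-nearest-neighbour
leave-one-out objective by gradient ascent with backtracking line search
(identity initialization, deterministic; the objective is non-decreasing
over accepted steps by construction). Activity classes for NCA are
response tertiles by default. LOF novelty scores delegate to
scikit-learn's classic reachability-density implementation (k = min(10,
n−1) neighbours; in-domain threshold 1.5, configurable); query points are
scored against the training cloud without joining it. Screening candidates
are always reported with their prediction and an in/out-of-domain flag,
never suppressed.

The packaged reference model (intercept −5.72; coefficients 7.90, 1.72,
−0.443, 0.161 on the four named descriptors) is immutable and
version-stamped; predictions decompose additively and convert to
r0 = 10^(sign · log-response) M s^-1.

## Synthetic data: what it emulates and what it does not

`make_point_molecules` draws uniform points in a 6 Å box with a 1 Å
minimum separation, elements from {C,H,N,O,P,Cl} plus exactly one
Ru/Rh/Os/Ir centre — enough geometric and elemental structure to exercise
metrics, cutoffs, normalizations, charge conservation and all invariances.
They are *not* chemically valid complexes: no valence rules, no realistic
bond networks, no conformational physics. Passing tests demonstrate
correctness of the descriptor algebra, not chemical realism of any
predicted rate.

`make_linear_qspr` draws equicorrelated standard-normal descriptors
(ρ = 0.2, population VIF 1.09) and a linear response with residual sd
0.21 log units at n = 25, k = 4 — the statistical geometry of the packaged
dataset, with default slopes chosen to give a generating R^2 of 0.90.
What it does not emulate: real descriptor distributions (skewed,
bounded), structural outliers, or any dependence between descriptors and
experimental conditions. `ga_pool_fixture` plants a known informative
subset in a wide pool for selection tests.

The packaged 32-record dataset carries the experimental conditions
(pressure, temperature, concentrations, solvent) and catalytic constants
as metadata only — the model is condition-free by design.

## Numerical choices and problem sizes

Sinkhorn: tol 1e-8, cap 10,000 alternations. Bond perception tolerance
0.25 on covalent-radii sums. PEOE: 6 iterations, damping 0.5. NCA: up to
200 accepted steps, 30 backtracking halvings, growth 1.1. Default seed for
stochastic operations: 20250430. Invariance tests run 200 random
molecules at 1e-9; LOVI-sum identities at 1e-10; the PRESS identity at
1e-10 over 100 random datasets; coefficient-recovery coverage over 500
simulations at n = 200; split-robustness summaries use 20–1000 splits
per dataset. These sizes were chosen to make the full suite a
desk-friendly run while keeping every statistical check well-powered.

## Known limitations

* Exact numerical agreement with external descriptor software is out of
  scope; the engine implements the framework with a documented,
  configurable grammar (the meaning of the `AB`/`nCi` tokens and the
  published N-tuple metric definitions are not public in detail).
* Order-3/4 tensors are dense; molecules beyond a few dozen atoms make
  order-4 descriptors expensive (O(n^4) memory).
* DS (Sinkhorn) normalization and matrix powers are order-2 only.
* Molecules with exactly degenerate principal moments have an ambiguous
  canonical frame (descriptor values may differ between equivalent
  orientations for p ≠ 2 metrics).
* The geometry-error utilities (MUE/MSE/%Er) compare externally supplied
  parameter lists; the package performs no geometry optimization.
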