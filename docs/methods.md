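# Methods

## Model and assumptions

The factorization assumes each view's score matrix is, up to noise, a
co-complex affinity of the form A⁽ᵐ⁾ = H_c H_cᵀ + H_s⁽ᵐ⁾ H_s⁽ᵐ⁾ᵀ: proteins
interact in proportion to the product of their memberships, complexes shared
between sources live in H_c, and structure seen by only one source lives in
that view's H_s⁽ᵐ⁾. Scores are compared to the reconstruction with the
generalized KL divergence D(W‖A) = Σ θᵢθⱼ[W log(W/A) − W + A], restricted by
the coverage mask θθᵀ so that proteins a source never observed contribute
nothing. The diagonal is inside the mask: self-scores are removed from W at
load time, so the fit slightly shrinks memberships to account for A_ii > 0 =
W_ii. This mirrors how the loss is defined and is shared by all views, so it
does not bias the shared/specific split.

Generalized KL (rather than least squares) is the natural loss for
nonnegative score matrices with many exact zeros and a heavy right tail; it
never penalizes a zero score with infinite weight, and it yields
closed-form multiplicative updates.

## Optimization

The objective is non-convex jointly but amenable to alternating
minimization. Each block is updated with a *damped* multiplicative rule,
new = old/2 + old/2 · (numerator/denominator), e.g. for the shared block

    H_c ← H_c/2 + ½ H_c ⊙ [Σ_m (Θ⁽ᵐ⁾⊙W⁽ᵐ⁾ ⊘ A⁽ᵐ⁾) H_c] ⊘ [Σ_m Θ⁽ᵐ⁾H_c + λH_c]

with Θ⁽ᵐ⁾ = θ⁽ᵐ⁾θ⁽ᵐ⁾ᵀ. The updates preserve nonnegativity exactly (a zero
entry is absorbing) and empirically decrease the objective monotonically;
an increase beyond 1e-9·|J| is logged as a warning rather than treated as
fatal, since the damped form has no published convergence proof. One sweep
costs O(N²K_c + 2N²K_s); with dense N×N masks the whole fit is quadratic in
N at fixed K.

**Stopping.** |J_t − J_{t−1}| / max(|J_{t−1}|, ε) < 1e-6, or 200 iterations.

**Restarts.** 20 by default. Initial factors are i.i.d. uniform(0,1) —
strictly positive, so no entry starts in the absorbing zero state. Each
restart draws from a child stream spawned off the master `seed` via
`numpy.random.SeedSequence`, making individual restarts independent and the
whole fit reproducible bit for bit. The restart with the lowest final
objective wins.

**Numerical guards.** ε = 1e-12 floors every log argument, every ratio
denominator A, and the update denominators. With all-zero factors the
objective is finite (log ε) rather than −∞.

## Parameters

| parameter | default | meaning |
|---|---|---|
| K | min(2500, 2N) in the CLI | total latent dimensions (complex budget); 2500 is the published genome-scale default and should scale with input size |
| η | 0.5 | shared fraction K_c/K; K_c = round(ηK), nudged ±1 (preferring larger) so K − K_c is even and K = K_c + 2K_s holds exactly |
| λ | 4.0 | weight of the trace-norm surrogate; larger λ prunes more latent dimensions. 4.0 is the genome-scale default; desk-scale fits in the tests and acceptance script use λ = 0.5, appropriate for N ≈ 60 inputs whose per-entry signal is O(1) |
| tol | 1e-6 | relative objective-change stopping threshold |
| max_iter | 200 | iteration cap per restart |
| n_restarts | 20 | random restarts |
| ε | 1e-12 | numerical floor |
| min_size | 3 | smallest reported complex, matching the standard evaluation protocol; applied to our own output for symmetry with competitors |

## Discretization

Per row of Ĥ = [Ĥ_c, Ĥ_s⁽¹⁾, Ĥ_s⁽²⁾], values are sorted descending and the
cut K_i ∈ {1, …, K−1} with the largest drop between consecutive sorted
values is chosen; all entries ≥ the K_i-th sorted value become 1, so a
protein can belong to several complexes. Ties go to the smallest K_i
(fewest assignments); the gap to an implicit zero beyond the last column is
not a candidate, so no protein is assigned everywhere; a constant positive
row keeps a single gap position but thresholds at its common value
(assigning the whole row — degenerate and essentially never seen after
fitting); an all-zero row gets no assignment and the protein is reported
unclustered. Complexes below `min_size` members are dropped and identical
member sets deduplicated (first column label kept, labels record the source
block: `k3.c`, `k5.s1`, …).

## Evaluation metrics

Sn = Σᵢ maxⱼ T_ij / Σᵢ nᵢ and PPV = Σⱼ maxᵢ T_ij / Σⱼ |∪ᵢ(bᵢ∩qⱼ)| with
T_ij = |bᵢ ∩ qⱼ|; Acc = √(Sn·PPV). Matching uses the overlap score
|b∩q|²/(|b||q|) ≥ ω with ω = 0.25, boundary inclusive. TP counts *predicted*
complexes matched by some reference complex while FN counts *reference*
complexes matched by nothing — the asymmetry is deliberate and follows the
standard protocol. FRAC is the fraction of reference complexes matched at
least once. Degenerate cases are total: PPV with an empty denominator,
F-measure with P + R = 0, all define the value as 0 with a warning.

The hypergeometric enrichment P-value defaults to the standard upper tail
P(X ≥ x) (scipy's survival function). A printed variant that starts the
cumulative sum at y = 1 — thereby omitting the zero-overlap term, a form
that circulates in the complex-detection literature — is available as
`as_printed=True`; for x ≥ 2 it exceeds the proper tail by exactly the y = 0
term. Reference preparation restricts complexes to the input universe,
drops those below 3 members after restriction, and optionally excludes
complexes identical (or, behind a flag, ω-matching) to a tuning catalog;
exclusion-by-exact-equality is the default because the protocol's notion of
"present in" another catalog is not otherwise pinned down.

## Synthetic benchmark generator

`generate` plants binary-support factors (entries equal to
`membership_strength` on the support) and emits W⁽ᵐ⁾ = clip(H_c H_cᵀ +
H_s⁽ᵐ⁾H_s⁽ᵐ⁾ᵀ + symmetric 𝒩(0, σ²), 0) with a zeroed diagonal and optional
per-view coverage masks. Complex sizes are drawn uniformly from
`complex_size_range` (default 6–10) conditioned on summing to ≥ N, and
supports are consecutive arcs on a random permutation spaced proportionally
to the cumulative sizes: the supports jointly cover every protein, and arcs
overlap exactly where the total size exceeds N. Covering supports are the
right benchmark for this method because the largest-gap discretization
assigns every covered protein to at least one complex — planting proteins
that belong nowhere would measure the discretizer's behavior on background
rows, not recovery of planted structure.

What the generator does *not* emulate: the degree distributions and score
distributions of real FSWeight/PE networks, bait–prey purification
structure, correlated noise, or contaminant proteins outside any complex.
Passing recovery tests therefore show that the optimization and
discretization recover the model's own generative structure under additive
noise and partial coverage — not that the method attains any particular
accuracy on real interactome data.

## Problem sizes used in tests

Oracle-equivalence checks run at N ≤ 10 against index-by-index loop
implementations (1e-10 relative agreement). Convergence and recovery checks
use N = 50–60, K = 8 (4 shared + 2×2 specific), 10–20 restarts, and a noise
grid σ ∈ {0, 0.1, 0.3, 1.0} averaged over 10 seeds — sizes at which the
full suite completes in well under a minute per property while still
exercising partial coverage, restarts and the full pipeline.

## Known limitations

- Exactly two views; the update rules are written for m = 1, 2.
- Dense N×N arithmetic; genome-scale inputs (N ≈ 6000, K = 2500) fit in
  memory but a single fit takes hours at 20 restarts.
- No automatic K/λ selection beyond the λ-driven rank suppression; tuning
  against a held-out catalog is the caller's job.
- The damped multiplicative update's monotonicity is checked empirically,
  not proved.
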