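# Methods

## The model

The ribosome's two subunits accreted their protein shells while the
genetic code was still expanding, so each universally conserved protein
position should carry an imprint of the code as of that protein's
recruitment. Two further assumptions turn this into an inference
procedure:

1. **Assembly recapitulates chronology.** The experimentally determined
   binding dependencies of subunit assembly (which proteins must bind
   before which) constrain the order in which proteins were recruited
   over evolutionary time. A *permitted linear evolutionary order*
   (PLEO) is any total order consistent with the dependency DAG — a
   linear extension of the partial order.
2. **Shared code pressure.** Both subunits evolved under the same
   expanding code, so chronology positions of similar age should show
   similar amino-acid usage bias, which is what allows the two
   chronologies to be aligned against each other.

### Chronologies

For a rule set on `n` proteins, the REO (ribosomal evolutionary order)
matrix gives `P[j, i]`, the probability of protein `j` occupying
chronology position `i` across permitted orders. We compute it exactly
by dynamic programming over downward-closed subsets (`O(2^n · n)`),
without enumeration: with `g(S)` the number of valid orderings of prefix
set `S` and `f(S)` the number of completions, the weight of "`j` at
position `|S|+1`" is `Σ_S g(S)·f(S ∪ {j})`. The same DP counts linear
extensions, drives an exactly-uniform sequential sampler (choice
probabilities proportional to completion counts), and — conditioned on a
"kept" subset — recompiles probabilities after deleting proteins that
must carry zero weight, with remaining proteins closing ranks. A cheaper
"frontier" sampler (uniform among currently bindable proteins) is
retained for sensitivity analysis; it is biased toward orders with few
choice points and is never the default.

Proteins excluded from usage averaging but kept in the ordering model:
L15 and L16 for the large subunit, S6, S16, S18 and S20 for the small
subunit — likely non-orthologous displacements whose universally
conserved positions cannot be called.

### Usage profiles

Conserved sites are called from per-site ancestral-state probabilities
at the two nodes flanking a root: the same amino acid must reach
probability ≥ 0.90 at both (the boundary is inclusive). Sites conserved
in both the bacterial and archaeal/eukaryal ancestors with identical
identity are universal (U); each domain's remainder is domain-specific,
pooled into the D dataset. A site conserved in both domains with
*different* identities contributes to both domains' D sets (a choice the
source material leaves open; it is recorded in output metadata).

Counts normalise to rates per protein, and positions get
probability-weighted deltas

    D_iA = Σ_j P_ij (U_jA/U_jT − D_jA/D_jT)

whose 20 values sum to zero at every position. The literal
count-difference quotient `(U_jA − D_jA)/(U_jT − D_jT)` is available as
a variant (`count_quotient`) but is not the default: it is undefined
when a protein's U and D totals coincide and its values do not sum to
zero, breaking the expected-value interpretation. The weighted standard
error is `sqrt(Σ_j P_ij² Var_j[A])` with binomial per-protein variances
`Var_j[A] = rU(1−rU)/U_jT + rD(1−rD)/D_jT`; this is a modelling choice —
it treats the REO weights as fixed and the per-protein compositions as
independent binomial draws.

### Residual matrix and structure test

The raw RMSD matrix compares every LSU position with every SSU position
over the 20 deltas. Its structure is partly artifactual: adjacent
positions are weighted averages over overlapping protein sets, and
terminal positions average fewer proteins (higher variance). The
permutation background — intact per-protein (U, D) vector pairs
reassigned uniformly across proteins within each subunit, profiles and
RMSD recomputed, entries averaged over replicates (default 10,000) —
preserves exactly that weighting structure while destroying any
recruitment-time signal. Keeping each protein's U and D vectors paired
is the default (it preserves the per-protein variance structure);
independent U/D permutation is available behind a flag. Raw minus
background is the residual. Structure is tested by one-sample Z against
fresh permutation replicates, for both the variance and the mean of
residual entries, one-tailed in the "actual exceeds randomized"
direction; the replicate spread uses the sample standard deviation of
the replicate statistics.

### Path landscape and alignment

Constrained monotone random walks traverse the residual matrix: start
uniformly on the first row or column (corner counted once); steps are
down, right, or diagonal, all in-bounds options equally likely, except
that a right step may not follow a down step nor vice versa (this keeps
every pairwise position in a path exclusive); a walk terminates the
moment it reaches the last row or column (the stated rules do not say
whether walks may crawl along the terminal edge; immediate termination
is the implemented choice, and cells of the first row/column that also
lie in the last row/column are legal one-cell walks). The score is the
mean residual over visited cells. The best-scoring 5% and 1% of walks
are compiled into per-cell frequency landscapes — the probabilistic
alignment of the chronologies.

A discrete alignment is extracted either as the single best-scoring walk
(default; ties broken lexicographically on the cell list) or as the
monotone path through the landscape maximising *mean* cell frequency
("ridge"; mean, not total, so length is not rewarded). An exact optimum
over all legal walks is computed by a layered dynamic program (minimum
path total per cell, last move and path length, minimising total/length
over terminal states); because walks are scored by mean over a
variable-length path, plain shortest-path recursion does not apply. This
exact optimum, and a brute-force walk enumerator for small matrices,
serve as cross-checks for the stochastic search — the landscape, not
just the optimum, is the method's output, which is why random walks are
retained.

### Congruence and convergence

Per amino acid, aligned positions get two-sample scores
`Z_c = (D_L − D_S)/sqrt(SE_L² + SE_S²)`, congruent when `|Z_c| < 1.282`
(the one-tailed 10% quantile, applied to the absolute score). Positions
combine by a weighted Z-transform, `Z_w = Σ w_c Z_c / sqrt(Σ w_c²)` with
inverse combined-variance weights, two-tailed normal p. Convergence per
chronology is `Z_V = |D_last|/SE_last − |D_first|/SE_first` at the
alignment's endpoint pairs, each chronology evaluated on its own
profile: convergent below −1, divergent above +1, and "consistently
convergent" when at least one chronology is convergent, neither is
divergent, and their mean is below −1. Degenerate cells (an amino acid
absent from every contributing protein: zero delta, zero SE) count as
congruent with zero signal and are dropped from the weighted
combination. No multiple-testing correction is applied across the 20
amino acids.

## The synthetic generator

The generator produces worlds at the level the pipeline consumes —
counts and probability profiles, no sequences or trees. Defaults define
the reference test conditions:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | (15, 18) | proteins per subunit analogue |
| `lag` | 3.0 | LSU-analogue head start, in recruitment spacings |
| `drift` | 0.9 | imprint effect size in [0, 1]; 0 = null world |
| `tau` | 4.0 | decay timescale of the recruitment bias, spacings |
| `sites` | (150, 200) | U and D conserved positions per protein |
| `dep_density` | 0.2 | probability of a dependency edge per earlier protein |
| schedule | −4 … 10 | amino-acid addition times (consensus order, linear) |

Recruitment times are unit-spaced; the addition schedule follows the
broad consensus temporal order of code expansion (G, A, D, V early; F,
C, M, H, Y, W late) and completes about two thirds of the way through
the combined recruitment window, so late additions visibly converge
toward modern usage within the observed chronologies. A protein
recruited at time `t` draws its U positions from weights
`modern_A · (1 − drift · s_A(t))`, where the suppression `s_A(t)` is 1
before amino acid A is added and decays as `exp(−(t − t_add)/tau)` after
(a step-function variant is included); D positions are drawn from modern
frequencies. `drift = 0.9` represents a strong imprint softened by
post-recruitment substitution; `drift = 1` would remove unavailable
amino acids entirely.

Two consequences of this design matter for interpreting tests. First,
compositional closure: suppressing late amino acids necessarily
over-represents the available early ones, so early amino acids start
*above* expectation and converge downward while late ones converge
upward — both classes show negative Z_V, and group-level contrasts (the
six latest additions vs the four earliest) are the meaningful readout.
Second, the per-protein site counts (150 U / 200 D) sit at the
optimistic end of what conserved-position datasets provide; they were
chosen so that the generator's planted effects stand clearly above
multinomial noise at testbed scale. Passing tests therefore demonstrate
correctness of the machinery under recoverable conditions, not
statistical power on field data, where conserved-position counts per
protein are far smaller and signals correspondingly weaker.

What the generator does not emulate: alignment error, tree and
ancestral-reconstruction uncertainty (profiles get a single
symmetric-noise parameter instead), heterogeneity of per-protein site
counts, lineage-specific composition, and any dependence between a
protein's usage and its position in the dependency DAG beyond
recruitment time.

## Numerical and procedural choices

- Positions and sites are 1-based in all I/O; matrices are 0-based
  internally.
- Enumeration order of permitted orders is lexicographic in protein
  labels; sampling is exactly uniform by default, and every stochastic
  operation takes an explicit seed (the pipeline derives per-stage seeds
  from one master seed via a seed sequence).
- The subset DP refuses `n > 24` (memory), enumeration refuses more
  than 1e8 orders and points to the sampler.
- Sampled-chronology convergence is diagnosed as the mean absolute REO
  entry difference between n and 2n samples.
- TSV (UTF-8, dot-decimal) is the canonical tabular format; matrices
  carry 1-based position headers; the pipeline manifest records
  versions, config, derived seeds and artifact names, and a rerun with
  the same config is byte-identical.
- Analysis scripts use 2,000 background permutations, 100 randomized
  replicates and 100,000 walks (20,000 samples for the sampled SSU
  chronology): sizes at which the Monte-Carlo error of every reported
  quantity is well below the effects examined, while a full run stays
  interactive.

## Known limitations

- **The weighted Z-transform is anticonservative on chronology data.**
  Aligned positions are weighted averages over overlapping protein
  sets, so their Z scores are strongly positively correlated (adjacent
  positions reach r ≈ 0.7 under null simulations), while the
  combination assumes independence. Marginal per-position Z scores are
  calibrated (std ≈ 0.96 under the null), and the combination is exact
  for independent inputs, but per-amino-acid p-values along a real
  alignment overstate significance. The permutation-based structure
  test does not share this problem (its null is generated by the same
  weighting model) and is calibrated under null worlds.
- The residual-based walk score has no gap or scoring-scheme
  generalisation; only mean residual is supported.
- Condensing the landscape into one discrete alignment is
  underdetermined; best-walk and ridge extractions are both provided
  and can disagree in flat regions of path space.
- The two real rule sets ship as versioned fixtures transcribed from
  published assembly maps (headers document the anchoring); the LSU
  transcription is validated against its published exact order count,
  the SSU transcription has no comparable check.
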