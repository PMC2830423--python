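# ribochron

Inference of ribosomal protein evolutionary chronologies from subunit
assembly maps, and of genetic-code history from the amino-acid usage
imprint those chronologies carry.

Ribosomal proteins were recruited onto an RNA core while the genetic
code was still expanding, so universally conserved positions in each
protein preserve a compositional imprint of the code at recruitment
time. Experimentally determined assembly maps — which proteins must bind
before which — constrain the possible recruitment orders. `ribochron`
turns these two observations into a pipeline for researchers in
molecular evolution:

1. **rules / pleo** — read binding-dependency rule sets as DAGs; count,
   enumerate, or uniformly sample the permitted linear evolutionary
   orders (PLEOs = linear extensions); compile the REO matrix `P[j, i]`,
   the probability of protein *j* at chronology position *i*, exactly by
   subset dynamic programming.
2. **usage** — call conserved sites from ancestral-state probabilities
   (≥ 90% at both nodes flanking the root), classify universal (U) vs
   domain-specific (D) positions, and build per-position weighted usage
   deltas `D_iA = Σ_j P_ij (U_jA/U_jT − D_jA/D_jT)` with weighted
   standard errors.
3. **chronology** — pairwise LSU×SSU RMSD over the 20 amino-acid deltas,
   a permutation background (usage vectors reassigned across proteins)
   that absorbs model artifacts, the residual matrix, and one-sample Z
   tests of its variance/mean structure.
4. **pathwalk** — constrained monotone random walks through the residual
   matrix; best-scoring path-frequency landscapes (top 5%/1%); extraction
   of a discrete chronology alignment (best walk, or landscape ridge).
5. **congruence** — per amino acid: two-sample Z scores at aligned
   positions, a weighted Z-transform combination with two-tailed p,
   endpoint convergence scores `Z_V = |D|/SE(last) − |D|/SE(first)`, and
   congruent/convergent/divergent calls.
6. **synthetic** — a generator of ground-truth worlds (code-expansion
   schedule, recruitment lag, usage drift, dependency DAGs, noisy
   ancestral profiles) so every stage is testable without external data.

The LSU and SSU rule sets ship as documented fixtures
(`src/ribochron/data/*.rules`); the large-subunit map admits exactly
30,298,800 permitted orders, which is the validation anchor for its
transcription. See `docs/methods.md` for the model, parameter meanings
and limitations.

## Worked example

```python
import ribochron as rc

# permitted orders of the large-subunit assembly map
lsu = rc.load_builtin_ruleset("LSU")
print(rc.count_pleos(lsu))          # 30298800

# a synthetic world with a known 3-position LSU head start
w = rc.simulate_world(seed=1)
L, S = w.subunits["LSU"], w.subunits["SSU"]
reoL, reoS = rc.reo_matrix(L.ruleset), rc.reo_matrix(S.ruleset)
dL, dS = rc.delta_profile(reoL, L.usage), rc.delta_profile(reoS, S.usage)
raw = rc.rmsd_matrix(dL, dS)
bg = rc.background_matrix(L.usage, S.usage, reoL, reoS, reps=2000, seed=2)
res = rc.residual_matrix(raw, bg)
aln = rc.extract_alignment(rc.random_walks(res, 100_000, seed=3))
print(aln.pairs[0])                  # (6, 1): early LSU positions lead
rep = rc.congruence_table(dL, dS, aln)
print(round(rep.z_v_lsu_ave, 3))     # -2.115: average convergence toward
                                     # modern usage along the chronology
```

The analysis scripts under `analysis/` run these stages in order on the
shipped maps and the reference synthetic world, printing what each step
found and writing tables under `results/` — e.g. `05_residual_structure.py`
reports that the actual residual matrix has variance 6.5e-05 against
1.8e-05 for its own randomizations (one-tailed p < 1e-4), and
`06_alignment_congruence.py` recovers an early LSU offset of +5 positions
(simulated truth +3) with grand convergence averages
Z_V,L(ave) = −2.115, Z_V,S(ave) = −1.983.

A CLI mirrors the library (`ribochron pleo-count --ruleset …`,
`ribochron run --config …`); every stochastic subcommand takes `--seed`.

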