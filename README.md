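# nnsym — spatial symmetry tests for nearest-neighbor structure

When two or more classes of points share a region — tree species in a
forest plot, cell types in a tissue section, cases and controls on a map
— their interaction leaves a signature in the nearest-neighbor (NN)
relations.  `nnsym` tests two kinds of *spatial symmetry* between
classes:

* **symmetry in the mixed NN structure** — do class-*i* points serve as
  NN to class-*j* points as often as the reverse?  The null is
  E[N_ij] = E[N_ji], where N_ij counts base points of class *i* whose NN
  is of class *j* (an off-diagonal cell of the k×k nearest-neighbor
  contingency table, NNCT);
* **symmetry in the shared NN structure** — do the classes have the same
  distribution of "times serving as a NN"?  The *Q-symmetry table*
  cross-tabulates class against NN-serving count m ∈ {0, 1, …, 5} (a
  planar point serves at most six times, almost surely at most five).

The tests, for completely mapped or sparsely sampled data:

* **McNemar / Bowker chi-square** and its **exact binomial** version on
  (N_ij, N_ji) — valid only for sparsely sampled base–NN pairs; on
  completely mapped data they are extremely conservative and every
  result carries a warning recommending the label-randomization version;
* **Dixon's Z_D** = (N_12 − N_21)/√Var[N_12 − N_21], with exact first
  and second moments under random labeling (RL) of the observed NN
  digraph, expressed in the class sizes and the digraph summaries Q
  (ordered pairs of points sharing a NN) and R (twice the reflexive
  pairs); the multiclass version forms T_S = (N_ij − N_ji)_{i<j} and the
  quadratic form X²_D = T_S′ Σ_sym⁻ T_S with a Moore–Penrose inverse;
* **Pearson chi-square on the (reduced) Q-symmetry table** with expected
  counts n_i·Q_m/n and df (k−1)(c−1);
* **exact conditional tests** on the Q-symmetry table: table probability
  under fixed margins, full enumeration, and the five two-sided p-value
  variants (table-inclusive, -exclusive, twice-inclusive, mid-p,
  Tocher-randomized), plus a Monte Carlo mode for larger tables;
* **post hoc analysis** for k > 2: restricted/unrestricted pairwise and
  one-versus-rest tests;
* **pattern simulators** (CSR, RL over uniform and Matérn-cluster
  backgrounds, and six structured alternatives) with a Monte Carlo
  harness for empirical size and power;
* **asymptotic power utilities**: first-order local power of chi-square
  tests and Pitman efficiencies (PAE(Z_I) = 4,
  PAE(Z_D) = 1/(ν₁(1−ν₁)p_q)).

## Worked example

The package ships the published NN contingency tables of the Lansing
Woods survey (black oak, maple, white oak; 1097 trees).  Shared-NN
symmetry for the three species:

```python
>>> import nnsym as ns
>>> t = ns.datasets.load_qsym("lansing_qsym")
>>> r = ns.pielou_q_symmetry(t)
>>> round(r.statistic, 3), r.df, round(r.p_value, 4)
(16.595, 4, 0.0023)
```

The chi-square of 16.6 on 4 df (p ≈ .002) rejects shared-NN symmetry:
the species differ in how often their members serve as nearest
neighbors.  One-versus-rest follow-ups localize it:

```python
>>> for name in ("lansing_ovr_qsym_bo", "lansing_ovr_qsym_wo"):
...     r = ns.pielou_q_symmetry(ns.datasets.load_qsym(name))
...     print(name, round(r.statistic, 3), round(r.p_value, 4))
lansing_ovr_qsym_bo 0.049 0.9758
lansing_ovr_qsym_wo 13.832 0.001
```

Black oaks are symmetric with respect to the other species (χ² = 0.05);
white oaks deviate strongly (χ² = 13.8, p = .001) — they serve as NN
less often than their abundance predicts.

From raw coordinates, the same analysis is one call per step
(`nearest_neighbors` → `build_nnct` / `build_qsym` → tests), or from a
shell:

```sh
nnsym test pattern.csv --seed 1          # all overall tests, JSON report
nnsym posthoc pattern.csv --mode all
nnsym simulate --family csr --n1 50 --n2 50 --nmc 10000 --seed 1
```

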