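# herdnet

Social-network analysis of managed cattle herds, for behavioural
ecologists and welfare researchers who work with scan-sampled
nearest-neighbour observations and agonistic interaction logs.

Farmers move animals between groups for breeding and pasture management,
so a herd's composition changes repeatedly over an animal's life. Each
episode of stable membership (a *composition*) yields a social network:
the dyadic association weight of two animals is the number of scans in
which one was the other's nearest neighbour. `herdnet` turns the raw
tables into:

* **dominance hierarchies** — Modified David's Score (MDS) from win/loss
  matrices, `DS_i = w_i + w2_i − l_i − l2_i` with chance-corrected dyadic
  indices `D_ij = P_ij − (P_ij − ½)/(n_ij + 1)`;
* **individual centralities** — strength `s_i = Σ_j a_ij` and eigenvector
  centrality (entry of the dominant eigenvector of the association
  matrix), corrected for group size before regression;
* **homophily tests** — Mantel correlations of the association matrix
  with age-, rank- and sex-difference matrices per composition, combined
  across compositions with Fisher's method;
* **mixed-model inference** — Gaussian GLMMs of (corrected) centralities
  on age, sex, dominance rank and familiarity with a random intercept per
  individual; all-subsets AICc model averaging with relative variable
  importance (RVI), node-label permutation p-values and VIF diagnostics;
* **transfer impact** — Mantel correlation of adjacent compositions'
  networks on shared members, per-individual centrality deltas, and the
  relation of network stability to the number of animals transferred.

No field data are bundled: a synthetic-herd generator with a known latent
hierarchy, homophily kernel and transfer timeline stands in for them, so
every stage is testable end to end (see `docs/methods.md` for the
generative model and what it does and does not emulate).

## Worked example

Generate a synthetic herd (two groups, seven compositions, transfers of
2, 1 and 0 animals) and run the full analysis:

```
herdnet simulate --seed 7 --out-dir herd7
herdnet all --input-dir herd7 --out-dir report --seed 7
```

or equivalently from Python:

```python
from herdnet import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(out_dir="report", scenario_seed=7, seed=7))
```

The report bundle contains, among others:

`dominance/N1.csv` — MDS components and ranks for composition N1
(excerpt):

```
   id        w        w2        l        l2         ds  rank
ind00 2.558333  9.032080 7.441667 37.110255 -32.961508    11
ind02 7.953571 41.709743 2.046429  8.625417  38.991468     2
```

`ds` is the Modified David's Score (dominant animals positive, dominated
negative); `rank` 1 is the top of the hierarchy.

`homophily.csv` — Mantel tests per composition plus combined rows
(excerpt):

```
composition_id matrix_pair         r            p
            N1   assoc-age -0.624638 9.990010e-04
            N1  assoc-rank -0.499002 9.990010e-04
            N1   assoc-sex -0.073677 5.154845e-01
        GLOBAL   assoc-age       NaN 2.008014e-14
```

Negative `r` for the age pair means same-aged animals associate more
(age homophily); the GLOBAL row is the Fisher combination over the seven
compositions. The generator plants exactly this structure, so the
pipeline recovering it is the expected outcome.

`models/strength_terms.csv` — model-averaged GLMM of corrected strength:

```
       term  estimate  std_error  pperm_left  pperm_right   rvi
        age   -48.183     17.036       0.001        1.000 0.964
familiarity    35.746     12.591       1.000        0.001 0.923
       rank   -16.551     18.537       0.020        0.981 0.553
```

`pperm_left`/`pperm_right` are node-label permutation p-values (1000
permutations of the response within compositions); `rvi` is the summed
Akaike weight of the models containing the term. Here familiarity raises
strength (right-side p = 0.001) — the generator's familiarity bonus —
and the age and rank signs reflect this particular herd's draw.

`transfers.csv` / the manifest's stability block — across the five
composition changes the restricted-network Mantel correlations average
0.977 (range 0.943–0.996) and correlate negatively with the number of
animals moved (Spearman ρ = −0.74, permutation p = 0.2 at n = 5). The
near-1 stability is a property of the noiseless synthetic kernel, not a
field prediction; see the limitations section of `docs/methods.md`.

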