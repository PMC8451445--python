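# browsevuln

Classify understory plant taxa by their vulnerability to sika deer
(*Cervus nippon*) browsing, from three field evidence streams collected at
forest sites that differ in how long deer have been established:

* **vegetation surveys** — plot-level percent cover per species;
* **browsing-damage scores** — the mean damage grade
  MDG = (0·CL1 + 5·CL2 + 30·CL3 + 75·CL4)/N over four ordinal damage
  classes scored on N plant units per species and site (range 0–75);
* **diet DNA metabarcoding** — trnL P6-loop reads from deer feces,
  assigned to plant taxa by exact identity against a reference database
  and summarised as relative read abundances.

Per-species 4-point profiles over the deer-establishment classes
(pre-1978, 1979–2003, 2004–2011, 2012–2014) are clustered with K-means
(cluster count by the gap statistic), cluster centroids are translated
into semantics (coverage *decline*, damage *early*/*gradual*, diet
*recent*/*old*), and an editable rule table integrates them into six
vulnerability groups: **A** browsed early + coverage declined, **B**
browsed early + coverage unknown, **C** browsed late + declined, **D**
browsed late + unknown, **E/F** browsed or selected but coverage
unaffected. Community-level statistics (Shannon diversity GLMs,
Bray–Curtis PERMANOVA with site-blocked permutations, NMDS, dbMEM spatial
screening) support the same arms. A synthetic-study generator with
planted archetypes makes the whole pipeline testable without any field
data. It is aimed at quantitative ecologists studying ungulate–vegetation
interactions.

## Worked example

Run the full pipeline on a synthetic study drawn at the default design
(22 sites, 20 plots/site, 63 fecal samples, 60 species across planted
archetypes):

```python
from browsevuln import PipelineConfig, SimConfig, run

result = run(PipelineConfig(seed=11, simulate=SimConfig()))
for k in ("veg_permanova_R2", "richness_chi2", "k_coverage", "k_mdg",
          "k_reads", "n_g4_species", "group_sizes"):
    print(k, "=", result.summary[k])
```

prints

```
veg_permanova_R2 = 0.7173
richness_chi2 = 11.0998
k_coverage = 2
k_mdg = 3
k_reads = 3
n_g4_species = 8
group_sizes = {'A': 10, 'B': 8, 'C': 10, 'D': 8, 'E': 6, 'F': 6, 'unclassified': 0}
```

Reading: plant community composition differs strongly among
establishment classes (PERMANOVA R² = 0.72 of the Bray–Curtis variance),
species richness differs too (LR χ² = 11.1, d.f. 3), the coverage
profiles split into 2 clusters and the diet profiles into 3, eight
species are flagged as absent-where-deer-oldest-but-browsed-elsewhere,
and every planted archetype is recovered in its own vulnerability group
(the generator planted 10 A, 8 B, 10 C, 8 D, 6 E and 6 F species).

The same run is available from the shell:

```bash
browsevuln run --synthetic --seed 11 --out results/demo
browsevuln simulate --seed 3 --out study/ --fasta   # emit raw CSV + FASTA
browsevuln mdg --damage study/damage.csv --out mdg.csv
```

See `docs/methods.md` for the model, the cluster-semantics rules, and
what the synthetic generator does and does not emulate.

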