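# soilroot

Bacterial community-assembly analysis along the soil–root continuum.

Microbes move from bulk soil into the rhizosphere and on into the root
endosphere, filtered at each step by root exudates and host selection.
`soilroot` is a Python library for quantifying that succession from an OTU
count table (samples × OTUs) and sample metadata (compartment ∈ {bulk_soil,
rhizosphere, endosphere}, host variety, replicate):

* **Abundance sub-communities** — partition OTUs per group into abundant
  (relative abundance > 1%), moderate (0.01–1%) and rare (< 0.01%) taxa,
  with per-class counts, cumulative abundances and cross-group fold
  changes.
* **OTU flow** — classify each OTU's transition between compartments as
  enriched, depleted, emerging (root-specific recruit), filtered (excluded
  by the host) or unchanged, via Wilcoxon rank-sum tests on relative
  abundances with BH correction (volcano-style output).
* **Diversity** — Chao1 and Shannon with rank-sum comparisons; Bray–Curtis
  distances, principal coordinate analysis, and PERMANOVA
  (R² = SS_between/SS_total, seeded permutation test).
* **Assembly mechanisms** — the Sloan neutral community model, fitting the
  migration rate m in F(p) = 1 − I_d(Nmp, Nm(1−p)) to the occupancy–
  abundance relationship, with R², Nm, and a 95% prediction band; and
  Levins' niche breadth B = 1/ΣP² for habitat generalism.
* **Co-occurrence networks** — thresholded signed Spearman graphs
  (|ρ| > 0.6, adjusted p < 0.01), node and network topology including
  modularity, and robustness as natural connectivity
  ln((1/n)Σe^λ) under random or degree-targeted node removal.
* **Synthetic generators** — lognormal metacommunities, compartment
  gradients with truth labels, and individual-based neutral assembly, so
  every stage is testable end-to-end without sequencing data.

## Worked example: recovering a migration rate

```python
import soilroot as sr

meta = sr.simulate_metacommunity(sr.MetacommunityConfig(n_otus=500, seed=1))
cm = sr.simulate_neutral_assembly(
    sr.NeutralAssemblyConfig(m=0.1, N=1000, M=50, seed=3), meta
)
fit = sr.fit_ncm(cm)
print(f"fitted m = {fit.m:.4f} (Nm = {fit.Nm:.0f}), R^2 = {fit.r_squared:.3f}")
print(fit.partition_counts().to_string())
```

prints

```
fitted m = 0.0892 (Nm = 89), R^2 = 0.950
above      17
within    367
below      17
```

Fifty local communities of 1000 individuals were assembled neutrally at a
true migration rate m = 0.1; the fitter recovers m = 0.089 from the
occupancy–abundance cloud alone, neutral dispersal and drift explain 95% of
the occupancy variation, and 367 of 401 OTUs fall inside the 95% neutral
prediction band — the signature of stochastically assembled communities.
The `examples/` directory has one narrative script per capability
(partition, flow, diversity/ordination, neutral model, niche breadth,
networks).

## Command line

A thin CLI mirrors the library for shell use:

```bash
soilroot synth gradient --n-otus 800 --depth 30000 --seed 1 --out-dir data/
soilroot partition --counts data/counts.tsv --metadata data/metadata.tsv --out part.tsv
soilroot flow --counts data/counts.tsv --metadata data/metadata.tsv \
    --source bulk_soil --target rhizosphere:XLZ61 --out flow.tsv
soilroot run --config config.yaml --out-dir results/   # full pipeline
```

The pipeline writes partition summaries, per-transition flow tables,
diversity and ordination tables, NCM fits per group, niche breadth tables,
network edge lists/metrics/robustness curves, and a `report.json` stamped
with the software version and a config hash for provenance.

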