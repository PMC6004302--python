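# paleozone

Quantitative paleoecology of down-core microfossil assemblages, built
around the workflow used to reconstruct the history of Frame Lake
(Yellowknife, Canada) from Arcellinida (testate amoeba) counts: a lake
rendered fishless by decades of gold-mine arsenic fallout and
urbanization, whose sediments record a pre-disturbance baseline, an
arsenic-contamination phase, and a recent eutrophication phase.

The package is for paleolimnologists and community ecologists who need
the standard chain of assemblage statistics as tested, scriptable
pieces:

* **Screening** — per-sample probable-error test (total count T against
  pe = 1.96·s/√T) and per-taxon standard-error test
  (S_X = 1.96·√(X(1−X)/N) < X in ≥ 1 sample);
* **Indices** — Shannon diversity H = −Σ p_i ln p_i with lake-health
  bands (stable ≥ 2.5, transition 1.5–2.5, stressed < 1.5) and the
  difflugiid/centropyxid stress ratio D/(D+C) with the 0.55 cutoff;
* **Geochemistry** — 25% censoring screen with DL/2 substitution,
  aluminum normalization, redox tracer ratios (As/S, As/Mn, …), and
  second-stage redundancy reduction among elements;
* **Resemblance** — Bray–Curtis d = Σ|x_j−x_k| / Σ(x_j+x_k) on
  (optionally √-transformed) abundances; Euclidean matrices for
  environmental profiles;
* **Zonation** — CONISS (constrained incremental sum-of-squares
  clustering) with broken-stick selection of the significant zone count;
* **Inference** — one-way ANOSIM (R = (r̄_b − r̄_w)/(M/2)), RELATE
  (Mantel-type Spearman ρ between resemblance matrices), and Spearman
  profile correlations, all with seeded permutation p-values;
* **Ordination** — NMDS (isotonic regression + Guttman updates,
  Kruskal stress-1, multi-start);
* **Chronology** — piecewise-linear age–depth models with explicit
  hiatus sentinels;
* **Synthetic cores** — a Dirichlet-multinomial generator with a
  double-peaked contaminant coupled to the stress-taxon share, for
  end-to-end validation and recovery studies.

The printed data tables of the Frame Lake core (30 samples × 32 taxa
relative abundances, LOI fractions, ²¹⁰Pb/ash-layer ages, radiocarbon
dates) ship as fixtures.

## Worked example

```python
import paleozone as pz

registry = pz.frame_lake_registry()
counts   = pz.frame_lake_assemblage(registry=registry)   # 30 x 32, relative
rel      = pz.to_relative(counts)

# stress ratio down-core
prof = pz.index_profile(rel, registry)
print(prof.dc_ratio[6].round(2))          # 0.2   (sample 7: stressed)
print(prof.dc_ratio[16:].mean().round(2)) # 0.79  (pre-disturbance zone)

# zonation: CONISS + broken stick on the Bray-Curtis matrix
tree = pz.coniss(pz.bray_curtis(rel, expect_transformed=False))
k = pz.broken_stick_select(tree)
print(k, tree.zones(k))
# 3 [3 3 3 3 3 3 2 2 2 2 2 2 2 2 2 2 1 1 1 1 1 1 1 1 1 1 1 1 1 1]

# do the three zones differ? ANOSIM on the sqrt/Bray-Curtis matrix
biotic = pz.bray_curtis(pz.sqrt_transform(rel))
res = pz.anosim(biotic, tree.zones(k), n_perm=999, seed=1)
print(round(res.value, 3), res.p_value)   # 0.829 0.001

# when was each zone deposited?
model = pz.frame_lake_age_model()
print(model.assign_age(6.0), model.assign_age(17.0), model.assign_age(25.0))
# 2000.47 1962.69 below unconformity at 17.0 cm, age >7,000 BP
```

Reading: the ratio of contamination-sensitive difflugiids collapses to
0.20 in sample 7 and averages 0.79 in the deep zone; the core splits
into three significant zones (deepest = zone 1: samples 17–30, the
early-Holocene baseline; zone 2: samples 7–16, the arsenic phase;
zone 3: samples 1–6, the eutrophication phase); the zones are strongly
and significantly distinct (ANOSIM R = 0.829, p = 0.001); and the age
model dates the upper 17 cm to AD 1962–2012, with everything below the
unconformity older than 7,000 years BP.

The same analysis runs from the shell:

```sh
paleozone zonate assemblage.csv --out zones.csv
paleozone indices assemblage.csv --out indices.csv
paleozone simulate --seed 42 --outdir synthetic_core/
paleozone report --config run.yaml        # full pipeline, all stages
```

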