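# rhizotype

Analysis toolkit for randomized-block **root/shoot phenomics trials** — the
kind of experiment where a panel of crop genotypes (the motivating study is a
46-genotype industrial hemp panel) is grown in replicate blocks, plants are
imaged, and root-system-architecture and shoot traits are extracted per
plant. It is aimed at plant breeders and root biologists who have a per-plant
trait CSV (e.g. a RhizoVision Explorer export plus biomass weights) and want
the standard downstream battery:

- **Derived traits** — specific root length (SRL = total root length / root
  dry mass, m g⁻¹), root mass fraction, lateral root length/fraction
  (diameter classes 2+3), total biomass, root-to-shoot ratio.
- **Genotype effects and broad-sense heritability** — per trait, an F-test of
  the genotype effect controlling for block, variance components
  (σ²_g, σ²_b, σ²_e) by REML or balanced-design expected mean squares, and

  H² = σ²_g / (σ²_g + σ²_e / r),  r = number of replicate blocks.

- **Trait correlation structure** — pairwise-complete Pearson R/p/n matrices
  on genotype means, plus bivariate OLS fits (e.g. root vs shoot biomass).
- **Quadrant ideotype classification** — percentile ranks per trait; a
  genotype above the 50th percentile on *all* designated root traits and all
  shoot traits is a big-root/big-shoot (quadrant I) type, and so on through
  II (big root / small shoot), III (small/small), IV (small root / big
  shoot); genotypes mixed on either side are UNASSIGNED with a
  nearest-group resemblance.
- **Cluster stability** — PCA + K-means (k ∈ {3, 4} by default), clusterwise
  bootstrap Jaccard stability, and concordance (contingency table + adjusted
  Rand index) with the quadrant groups.
- **Culling sensitivity** — dioecious crops lose male plants after sexing;
  plots with extreme culling (≥ 4 plants removed, by default) are excluded
  and the analysis re-run to report which traits change significance.

A first-class **synthetic trial generator** simulates the whole design
(genotype, block and residual variance components per trait, a genetic
correlation matrix across traits, truncated-Poisson male culling) with known
ground truth, so every stage is testable without the original data.

## Worked example

Simulate a trial at the study design (46 genotypes × 3 blocks × 5 plants,
~2 plants culled per plot), derive traits, and analyze:

```sh
$ rhizotype simulate --seed 7 --out trial.csv --counts-out counts.csv
wrote 442 plants to trial.csv
$ rhizotype derive trial.csv --out derived.csv
$ rhizotype heritability derived.csv --out herit.csv
                  trait        F      p_value           H2
      total_root_length 2.213166 2.983313e-05 5.317393e-01
       root_dry_biomass 2.391139 4.449098e-06 6.115602e-01
      shoot_dry_biomass 3.932306 8.143682e-14 7.632821e-01
      ...
$ rhizotype classify derived.csv
quadrant
UNASSIGNED    25
III           11
I             10
$ rhizotype sensitivity derived.csv counts.csv
excluded 13.0% of plots; lost: []; gained: []
```

Reading the output: shoot dry biomass shows the strongest genotype signal
(F ≈ 3.9, H² ≈ 0.76 — the generator's configured truth for that trait is
0.77); most genotypes fall in the coherent big/big (I) and small/small (III)
quadrants because root and shoot size are strongly genetically correlated;
and dropping the ~13 % most-culled plots changes no trait's significance in
this replicate. The same run is available from Python:

```python
import rhizotype as rz
summary = rz.run_pipeline(rz.PipelineConfig(out_dir="out", seed=7))
```

which writes the full result bundle (trial, ground truth, heritability,
correlation matrices, quadrant table, cluster labels and Jaccard
stabilities, sensitivity report, `run_summary.json`) under `out/`.

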