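# plastisphere

Analysis toolkit for microbial and metazoan communities living on floating
plastic debris ("the plastisphere") and for the physical context those
communities inhabit. It is written for microbial ecologists and
oceanographers who have (a) surface-trawl particle measurements, (b)
light/dark bottle oxygen incubations, and (c) shotgun-metagenomic alignment
hit tables, and who want the standard chain of analyses connecting them:

1. **Particle size spectra** (`plastisphere.sizespec`). Diameters are binned
   into log10-spaced size classes (edges at `10^(k·0.1)` mm) and counts are
   normalized to linear bin width, giving the size-spectrum ordinate
   *A_n* (mm⁻¹). Steady-state fragmentation predicts *A_n ∝ d^−ξ* with
   ξ ≈ 3; `PowerLawSizeSpectrum` fits ξ by Poisson regression of the bin
   counts on log diameter (a log-log OLS variant is also provided) over
   bins above 3 mm, where surface trawls sample the spectrum faithfully.
   Trawl counts convert to fragments/m³ and, integrated over the upper
   0.15 m, to fragments/km².
2. **Bottle metabolism** (`plastisphere.metabolism`). From light, dark and
   time-zero oxygen bottles: NCP = (light − t0)·24/Δt, R = (t0 − dark)·24/Δt,
   GPP = NCP + R (exactly, by construction). Oxygen in plastic-amended
   bottles is displacement-adjusted to total moles over the water the
   particle leaves behind, and per-particle rates are obtained by
   subtracting unamended seawater rates. Chlorophyll helpers normalize
   Chl *a* to particle surface area and express it as an equivalent volume
   of seawater. Kruskal–Wallis + Dunn (BH) and Mann–Whitney/ANOVA group
   tests are included.
3. **LCA taxonomic profiling** (`plastisphere.taxonomy`). For each SSU rRNA
   read, alignment hits with length ≥ 100 bp and bit score ≥ 50 whose bit
   score is within 1% of the best qualifying hit are retained, and the read
   is assigned to the lowest common ancestor of the retained lineages (two
   hits in one family but different genera ⇒ family). Clade × sample counts
   become proportions under an explicit denominator, rounded to a fixed
   decimal place (a deterministic stand-in for rarefying), then square-root
   Bray–Curtis NMDS, thresholded family richness with Welch's t, and
   per-clade Mann–Whitney/BH group tests.
4. **KO functional comparison** (`plastisphere.funcomp`). Reads whose
   best-scoring protein hits (≥ 50 aa) are all bacterial take the KO of
   their top hit; KO counts become rounded proportions and are compared
   between groups with per-KO Mann–Whitney tests, BH FDR control, and
   enrichment flags at adjusted p < 0.005 and |log2FC| > 2.

`plastisphere.synthetic` generates seeded inputs for every stage — bounded
power-law diameters, Gaussian-noise bottles, hit tables with constructed
LCA ambiguity, and negative-binomial KO tables with planted fold changes —
so the whole pipeline runs and is validated without any external data.

## Worked example

```python
from plastisphere.synthetic import SimulationConfig, simulate_all
from plastisphere.sizespec import PowerLawSizeSpectrum
from plastisphere.metabolism import BottleRateEstimator
from plastisphere.taxonomy import LCATaxonomyClassifier, clade_table, round_normalize
from plastisphere.funcomp import MannWhitneyDifferentialAbundance

data = simulate_all(SimulationConfig(seed=42))

est = PowerLawSizeSpectrum().fit(data["diameters"])
print(f"exponent = {est.exponent_:.3f} (r^2 = {est.r_squared_:.3f})")

rates = BottleRateEstimator().fit(data["bottles"]).rates_["exp"]
print(f"NCP = {rates.ncp/0.125:.2f}, R = {rates.r/0.125:.2f}, "
      f"GPP = {rates.gpp/0.125:.2f} umol O2/L/day")

assignments = LCATaxonomyClassifier().fit(data["taxonomy"]).predict(data["hits"])
table = round_normalize(clade_table(assignments, rank="family", domain="Bacteria"), 2)
print(table.normalized)

de = MannWhitneyDifferentialAbundance(
    group_order=("plastic", "picoplankton")
).fit(data["ko_counts"], data["ko_groups"])
print(de.summary_)
```

prints

```
exponent = 3.201 (r^2 = 0.979)
NCP = 11.23, R = 4.43, GPP = 15.66 umol O2/L/day
sample             sample_1
clade
Flavobacteriaceae      0.22
Hyphomonadaceae        0.09
Microcoleaceae         0.40
Rhodobacteraceae       0.28
{'n_tested': 1998, 'n_up': 195, 'n_down': 2, 'pct_up': 10, 'pct_down': 0}
```

Reading the numbers: the size-spectrum fit recovers the generating
exponent 3 up to single-survey sampling spread; the bottle estimator
recovers the configured NCP = 10 and R = 5 µmol O₂/L/day within
measurement noise, with GPP identically their sum; the family table is the
rounded (hundredths) proportion profile of the synthetic biofilm
community; and the KO comparison flags 195 of the 200 planted 16-fold
enriched orthologs (and 2 false flags out of 1,998 tested) at FDR < 0.005.

A `plastisphere` console script exposes the same steps
(`plastisphere sizespec`, `metab rates`, `taxa assign|table|ordination|test`,
`ko assign|test`, `simulate`); every subcommand reads and writes plain TSV.

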