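# scannet

Social-network analysis of behavioural **scan-sampling** data from
group-living animals — built for studies that ask whether early-life
adversity (e.g. maternal loss or long-term solitary housing in captive
chimpanzees) leaves a lasting mark on an individual's social integration.

From instantaneous scan records of *passive close proximity* (who is within
arm's reach of whom) and *social grooming* (who grooms whom), the package:

1. builds weighted networks per group and observation period — undirected
   proximity edges and directed grooming-given edges, weighted as the
   percent of scans (0–100) in which the dyad showed the behaviour;
2. computes two individual measures with group-size standardisation:
   * **vertex strength centrality** `s_i/(N−1)` — mean percent of scans
     spent per potential partner;
   * **deviation from edge weight disparity**
     `dY₂ = Σ_j (w_ij/s_i)² − 1/(N−1)` — how far an individual's
     distribution of partners departs from an even spread (0 = even,
     higher = more restricted partner choice). Disparity is undefined for
     individuals with zero strength (e.g. animals that never groom) and
     such rows are excluded from disparity analyses;
3. compares deprivation classes (ND, EMD, ELD, LLD) with normal linear
   mixed models (identity link, random intercept per group), reduced by
   backward stepwise selection on the small-sample corrected AIC
   (`AICc = −2logL + 2k + 2k(k+1)/(n−k−1)`), with marginal type-III-style
   F tests per term;
4. runs post-hoc two-sided Mann-Whitney U tests (exact when untied and
   `n_a·n_b ≤ 400`) with Holm–Bonferroni correction per family.

Because raw field observations of this kind are rarely deposited, a
first-class synthetic generator reproduces the study structure (41 adults
in 4 groups, ~500 scans per group-period, class-graded sociability,
grooming propensity and partner selectivity), so every stage is testable by
parameter recovery. See `docs/methods.md` for the model details.

## Worked example

```python
from scannet import RunConfig, SyntheticConfig, run_analysis

cfg = RunConfig(seed=4, synthetic=SyntheticConfig(n_scans=500, periods=("2003",)))
bundle = run_analysis(cfg)

groom = bundle.measures.query("behaviour == 'grooming_given'")
print(groom.groupby("deprivation_class")[["strength_centrality",
                                          "disparity_deviation"]].median().round(3))
```

```
                   strength_centrality  disparity_deviation
deprivation_class
ELD                              0.600                0.754
EMD                              2.164                0.250
LLD                              2.800                0.410
ND                               2.987                0.093
```

Early long-term deprived (ELD) individuals groom a potential partner in a
median 0.6% of scans — a quarter of the non-deprived (ND) level — and the
grooming they do give is concentrated on very few partners (dY₂ 0.75
against 0.09 for ND). The selected model and post-hocs for this measure:

```python
report = bundle.models[("grooming_given", "2003", "strength_centrality")]
print(report.retained_terms)        # ('deprivation_class',)
print(report.results.summary())
```

```
Linear mixed model for network measure (strength_centrality, ML)
==================================================================
n = 41   groups = 4   k = 6
logLik = -56.270   AICc = 127.010
residual var = 0.86035   group var = 0.0675
converged = True   singular = False
------------------------------------------------------------------
Fixed-effect tests (marginal F):
             term        F  df1  df2      p
        Intercept 134.0213    1   37 0.0000
deprivation_class  14.3664    3   37 0.0000
```

```python
ph = bundle.posthocs.query(
    "behaviour == 'grooming_given' and measure == 'strength_centrality' "
    "and family == 'class'")
print(ph[["level_a", "level_b", "n_a", "n_b", "U", "p_holm", "significant"]])
```

```
level_a level_b  n_a  n_b    U   p_holm  significant
    ELD     EMD   10    7  0.0 0.000411         True
    ELD     LLD   10    8  0.0 0.000229         True
    ELD      ND   10   16  0.0 0.000002         True
    EMD     LLD    7    8 17.0 0.463714        False
    EMD      ND    7   16 31.0 0.307811        False
    LLD      ND    8   16 55.0 0.610093        False
```

Backward selection kept only the deprivation-class term (F₃,₃₇ = 14.4,
p < 0.001), and the Holm-corrected rank tests localise the effect: ELD
animals groom significantly less than every other class, while the
late-deprived (LLD) class does not differ from the non-deprived baseline.

## Command line

```bash
scannet simulate --seed 1 --out sim/                # synthetic roster + scan CSVs
scannet validate --roster sim/roster.csv --scans sim/scans.csv
scannet measure  --roster sim/roster.csv --scans sim/scans.csv --out meas/
scannet analyse  --config examples/demo.yaml --out report/
```

`analyse` writes the full report bundle: GraphML/edge-list networks, the
measure table, the model and selection-ledger tables, the post-hoc table,
and a manifest (config hash, seed, version) sufficient to re-run a
synthetic analysis bit-identically.

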