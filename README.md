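# wntscreen

Analysis of high-throughput **dual-luciferase Wnt reporter screens**:
plate normalization, toxicity-penalized activity scoring and hit
calling, assay quality control, structural clustering of hits by
atom-pair similarity, and prioritization of hits by predicted human
exposure. A seeded synthetic-screen simulator with known ground truth
makes every stage testable end to end.

It is written for screening and computational-toxicology groups who run
β-catenin-activated reporter (BAR) assays against environmental
chemical libraries (e.g. ToxCast-style collections) and need a
reproducible, scriptable version of the standard analysis.

## The analysis in brief

Each well reports firefly luciferase (Wnt-responsive) and *Renilla*
luciferase (constitutive; a viability/cell-number control). Per plate
and replicate day:

- **Wnt ratio** = (firefly / *Renilla*), median-centered within the
  plate (plate median = 1);
- **Cell Health** = raw *Renilla*, median-centered within the plate —
  a viability proxy, since pure toxicity depresses both channels and
  cancels in the ratio;
- **log2FC** = log2(Wnt ratio) relative to the plate's vehicle wells.

Replicates are averaged (plates within day, then days) and each
chemical × concentration is tested against the matched vehicle wells
with a two-sided Welch *t*-test. Per chemical the toxicity-penalized
score is

```
WntScore = mean_c(log2FC) × mean_c(CellHealth)
```

and hits require p < 0.05, |mean log2FC| > 1 and |WntScore| > 0.4
(activator vs inhibitor by sign), with concentration-dependent
toxicity flagged when the Cell-Health log2FC falls below −1 at
p < 0.05. Assay quality is tracked per plate with the Z-factor,
`1 − 3(σp + σn)/|μp − μn|`, and control sign checks that catch plate
swaps.

Hits are grouped structurally via Carhart atom pairs — multisets of
(atom type, shortest-path bond distance, atom type) with atom type =
(element, heavy-atom degree, π-count) — under counted Tanimoto
similarity, average-linkage hierarchical clustering, and classical
(Torgerson) multidimensional scaling. Finally, hits are ranked by
predicted human exposure (mg/kg-bodyweight/day, upper 95% CI, per
demographic) to prioritize follow-up. See `docs/methods.md` for the
full model, defaults, and limitations.

## Worked example

Simulate a small screen — 20 test chemicals, one a nontoxic Wnt
activator (Emax 4, EC50 1 µM) and one purely toxic (TC50 0.5 µM) — and
fit the analysis model:

```python
import wntscreen as w
from wntscreen.simulate import ChemicalTruth

truths = [ChemicalTruth("CHEM_0001", emax=4.0, ec50=1.0),
          ChemicalTruth("CHEM_0002", emax=1.0, tc50=0.5)] + [
    ChemicalTruth(f"CHEM_{i:04d}") for i in range(3, 21)]
cfg = w.ScreenConfig(n_test_chemicals=20, noise_sigma=0.2, seed=1)
wells, truth = w.simulate_screen(cfg, truths)

res = w.WntScreen.from_dataframe(wells).fit()
print(res.summary(top=8))
```

```
Wnt reporter screen summary
===========================
wells: 592   chemicals: 26   plates x days: 4
wnt score variant: legend
thresholds: alpha=0.05, |log2FC|>1.0, |WntScore|>0.4, toxic CH log2FC<-1.0
hit classes: activator=4, inhibitor=3, toxic=1, none=18

top 8 chemicals by |Wnt Score|:
chemical_id  mean_log2fc_all_conc  mean_cell_health_all_conc  wnt_score     min_p hit_class
 CTRL_ACT_3                 3.068                      1.016      3.116 1.006e-14 activator
 CTRL_ACT_1                 2.833                      1.089      3.085 6.307e-05 activator
 CTRL_ACT_2                 3.093                     0.9881      3.056 0.0001046 activator
 CTRL_INH_3                -2.876                     0.9526      -2.74 5.768e-05 inhibitor
 CTRL_INH_2                -2.624                     0.9281     -2.436 5.255e-07 inhibitor
 CTRL_INH_1                -2.689                     0.8716     -2.343 8.724e-06 inhibitor
  CHEM_0001                 1.305                      1.044      1.363  0.000483 activator
  CHEM_0013               -0.1263                      1.033    -0.1305  0.000172      none

median plate Z-factor: activators 0.199, inhibitors 0.156
```

Reading the output: the six spiked control chemicals segregate to the
top of the |Wnt Score| ranking with the expected signs, the planted
activator CHEM_0001 is recovered (mean log2FC 1.3 ≈ the mean of
log2(activity) over the dosing series, Cell Health ≈ 1 so no toxicity
penalty), the planted toxic chemical is classified `toxic` rather than
as a modulator, and the 18 inert chemicals stay below every threshold —
note CHEM_0013, significant by p-value alone but correctly rejected by
the effect-size thresholds. Positive plate Z-factors confirm the
controls separate from vehicle on every plate.

`res.scores`, `res.summaries`, `res.normalized` and `res.qc` are plain
DataFrames; `res.plot_volcano()` and `res.plot_health_vs_activity()`
draw the standard diagnostic scatters.

The same stages are available from the shell:

```bash
wntscreen simulate --seed 1 --out sim/
wntscreen score sim/wells.tsv --out scored/
wntscreen cluster chemicals.csv --cut-k 4 --out clusters/
wntscreen prioritize scored/scores.tsv exposure.csv --demographic females_16_49
wntscreen run --config run.json --simulate --seed 1   # full pipeline + manifest
```

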