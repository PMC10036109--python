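# letfoci

Tools for the quantitative chain linking a carbon-ion beam's **linear energy
transfer (LET)** to the **volume of γH2AX foci** (a microscopy proxy for
clustered DNA double-strand breaks) and to **clonogenic cell killing** at
1 Gy. It is aimed at radiobiologists and medical physicists who want to test
or reuse this inference chain — including on clinical spread-out Bragg peak
(SOBP) beams — without re-running microscopy or particle transport: a
synthetic-data generator reproduces the statistical structure of every input
table.

## The model

For carbon ions of LET *L* (keV/μm, clinically relevant range 13–100):

* The per-nucleus **maximum focus volume** *v* (μm³) of hit nuclei follows

  *f<sub>L</sub>(v)* = N(μ<sub>L</sub>, σ<sub>L</sub>),
  with μ<sub>L</sub> = 0.0158·*L* + 0.126 and σ<sub>L</sub> = 0.00724·*L* + 0.0312
  for A549 cells. The **clustering probability**
  *p<sub>L</sub>(v<sub>th</sub>)* = ∫<sub>v<sub>th</sub></sub><sup>∞</sup> *f<sub>L</sub>(v)* d*v*
  is the probability that 1 Gy induces a focus of volume *v*<sub>th</sub> or greater.

* The **unhit fraction** (cells with < 1% nuclear γH2AX occupancy, i.e. no
  particle traversal) follows R<sub>unhit</sub> = (0.0618·*L*)²/100, and
  R<sub>hit</sub> = 1 − R<sub>unhit</sub>.

* Clonogenic **killing** is 1 − SF (SF = colonies/seeded ÷ plating
  efficiency); dividing by R<sub>hit</sub> restricts killing to traversed cells.

* For mixed SOBP beams, each ridge-filter component *j* (weight w<sub>j</sub>,
  range shift s<sub>j</sub>) contributes LET L<sub>mono</sub>(z + s<sub>j</sub>)
  and dose d<sub>j</sub> = w<sub>j</sub>·D<sub>mono</sub>(z + s<sub>j</sub>) at the
  SOBP-center depth z; the **dose-averaged LET** is
  L<sub>mix</sub> = Σ L<sub>j</sub>d<sub>j</sub> / D with every component capped
  at 100 keV/μm (overkill region).

The concordance analysis sweeps candidate lethal-volume thresholds
v<sub>th</sub> and finds the one minimising the mean absolute difference
between *p*(v<sub>th</sub>) and R<sub>hit</sub>-normalised killing across
conditions — the threshold at which DSB clustering best predicts killing
(0.7 μm³ under the generating model).

## Worked example

The full synthetic pipeline — simulate foci/occupancy/clonogenic tables,
fit every law, sweep thresholds — in one command:

```sh
$ letfoci full-pipeline --seed 3 --out conc.csv
optimal v_th = 0.8 um^3 (mean |p - killing/R_hit| = 0.0212)
```

With this seed the fitted laws are μ = 0.01644·LET + 0.1608,
σ = 0.00705·LET + 0.0203 and unhit coefficient c = 0.0633 (truth: 0.0158,
0.126, 0.00724, 0.0312 and 0.0618); the recovered optimal threshold lands
one 0.1 μm³ grid step from the generating 0.7 μm³, with a mean
concordance gap of 2.1% across the six LETs. `conc.csv` holds the full
(condition, v_th, p, killing, difference) sweep and `conc.json` the
summary. The same stages are available piecewise (`simulate`, `fit-foci`,
`fit-unhit`, `survival`, `make-beam`, `mix-let`, `concordance`) and as
library functions:

```python
from letfoci import A549_LET_LAWS, clustering_probability
clustering_probability(0.7, 60.0, A549_LET_LAWS)   # 0.789089
```

For a clinical beam, `make-beam --width 30` builds a parametric
monoenergetic depth profile plus flat-SOBP ridge-filter weights, and
`mix-let` reports its dose-averaged LET (77.6 keV/μm at 30 mm width,
falling to 34.1 at 120 mm).

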