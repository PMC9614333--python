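# greyrank

Grey relational ranking of risk-factor time series against disease
burden, with a Hurwicz decision step for comparing diseases.

## The problem

Epidemiologists often need to order a handful of candidate risk factors
by how closely their trajectories track a disease-burden series — for
example, six dietary and nutritional exposures (diet low in fruits, diet
low in vegetables, diet high in sodium, vitamin A, zinc and iron
deficiency) against annual DALYs from ischemic heart disease (IHD) and
stroke, each series expressed as a percentage of the population over a
decade. With ~10 annual observations per series, regression-style
inference is fragile; grey relational analysis (GRA), a grey-systems
technique built for short, information-poor series, ranks factors by the
geometric similarity of their curves instead.

## The models

Series are normalized first (default: divide each series by its own
mean). For a reference series $Y_i$ and comparative $Y_j$ over epochs
$\ell = 1..h$, with deviations $\Delta_j(\ell) = |Y_i(\ell) - Y_j(\ell)|$:

**Deng's grade** (pointwise proximity), with distinguishing coefficient
$\zeta \in (0,1)$, conventionally 0.5, and extremes
$\Delta_{\min}, \Delta_{\max}$ taken over all comparatives and epochs:

$$\gamma_{ij} = \frac{1}{h}\sum_{\ell=1}^{h}
\frac{\Delta_{\min} + \zeta\,\Delta_{\max}}{\Delta_j(\ell) + \zeta\,\Delta_{\max}}$$

**Absolute grade** (integral proximity), from signed integrals
$\mathfrak{r} = \int_1^h Y^0\,dt$ of the zero-start images
$Y^0(\ell) = Y(\ell) - Y(1)$ (trapezoid rule on unit spacing):

$$\epsilon_{ij} = \frac{1 + |\mathfrak{r}_i| + |\mathfrak{r}_j|}
{1 + |\mathfrak{r}_i| + |\mathfrak{r}_j| + |\mathfrak{r}_i - \mathfrak{r}_j|}$$

**Second synthetic grade** (inclusive proximity), a convex blend with
$\vartheta \in [0,1]$, default 0.5:

$$p_{ij} = \vartheta\,\epsilon_{ij} + (1-\vartheta)\,\gamma_{ij}$$

All grades lie in $(0, 1]$; identical curves score exactly 1. Factors
are ranked per metric (a Pearson $r$ column is computed as a
conventional cross-check of the ordering). Finally the second-synthetic
grades form a diseases × factors payoff matrix scored by the **Hurwicz
criterion** with optimism index $\alpha$ (default 0.8):

$$h(A_k) = \alpha \max_p v(A_k, N_p) + (1-\alpha) \min_p v(A_k, N_p)$$

selecting the alternative that minimizes (default) or maximizes $h$.

## Worked example

Simulate two burden-like panels (10 annual epochs, 6 factors with a
planted similarity ordering), run the pipeline, and report:

```
greyrank simulate --seed 11 --out ihd.csv
greyrank simulate --seed 22 --out stroke.csv
greyrank run --panel IHD=ihd.csv --panel Stroke=stroke.csv \
             --reference burden --out results
greyrank report results/results.json
```

which prints (abridged):

```
== IHD ==
Factor    gamma      epsilon    p          pearson_r  rank (p)
factor_1     0.9984     0.9934     0.9959     1.0000          1
factor_2     0.9486     0.8158     0.8822     0.9903          2
...
factor_6     0.6420     0.5761     0.6091     0.9546          6
Ranking sequence: factor_1 > factor_2 > factor_3 > factor_4 > factor_5 > factor_6

== Hurwicz criterion (alpha=0.8, minimize) ==
IHD: 0.9185  <- selected
Stroke: 0.9274
```

The factors were generated with increasing shape distortion away from
the burden series, and all four metrics recover that planted order:
`factor_1` (no distortion) grades near 1 in every model, and grades
fall monotonically through `factor_6`. The Hurwicz line blends each
disease's best and worst second-synthetic payoff (h = 0.8·max +
0.2·min); under the minimization reading, the lower value (IHD, 0.9185)
marks the disease whose worst-case association with the factor set is
strongest.

The same analysis is available as estimators:

```python
import greyrank as gr

panel = gr.generate_panel(gr.SyntheticPanelConfig(seed=11))
ranker = gr.GreyRelationalRanker(zeta=0.5, theta=0.5).fit_panel(panel)
ranker.ranking_["p"]       # ['factor_1', ..., 'factor_6']
ranker.grades_             # gamma/epsilon/p/pearson_r + ranks per factor
```

`GreyRelationalRanker` follows the scikit-learn protocol
(`fit(X, y)` with comparatives as columns of `X`, `transform` reorders
or truncates columns by rank) and composes with sklearn pipelines.

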