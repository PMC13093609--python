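# mbs-cua

A Markov cohort cost-utility model of **metabolic and bariatric surgery
(MBS) versus usual care (UC)** for adults with obesity and comorbid
type 2 diabetes, built for health-economic analysts who want a tested,
scriptable re-implementation of a published hospital-system evaluation:
base-case cost-effectiveness, probabilistic and one-way sensitivity
analysis, and age × obesity-class scenario analysis.

## The model

Five health states — overweight (OW, BMI 25–29.9 kg/m²) and obesity
classes I–III (OB1/OB2/OB3), plus absorbing death — evolve over annual
cycles (default horizon 40 years, cohort entry age 52.4, entry mix
0.5/20/79.5% across OB1/OB2/OB3). Surgery applies an observed 12-month
class-change matrix at entry (with surgical mortality 0.5% combined
with background mortality as competing risks), then an upward BMI
drift of 1.8%/yr; usual care drifts up 6.03%/yr and down 5.57%/yr.
Background mortality is a two-anchor Gompertz life table, scaled by a
diabetes mortality risk ratio of 1.54 for the diabetic fraction of the
cohort (100% under UC; 10.1% post-surgery).

Per cycle, each alive state accrues a utility
`u_s − 0.003·(age − age₀) − 0.116·f` and a cost
`c_s·(1+g_s) + f·3997·1.05^t` (static OB2/OB3 class-cost differentials
of 5%/10%; diabetes costs compound 5% per year), discounted at 5%:

```
ΔC = C_surgery − C_UC,  ΔQ = Q_surgery − Q_UC
ICER = ΔC/ΔQ (or a dominance label),  NMB = λ·ΔQ − ΔC,  λ = A$64,000/QALY
```

PSA draws every uncertain parameter from moment-matched Beta/Gamma (or
Triangular) distributions and summarizes the cloud of (ΔQ, ΔC) points
on the cost-effectiveness plane; the one-way analysis produces a
tornado table of NMB excursions. Modelling conventions the published
description leaves open (inflator compounding, year-1 timing,
half-cycle correction, horizon mode, …) are explicit config flags —
see `docs/methods.md`.

## Worked example

```bash
$ mbs-cua base --out out/base --seed 1
UC: $229,980 / 6.116 QALYs | surgery: $143,574 / 9.269 QALYs | dC $-86,406, dQ 3.153, ICER dominant, NMB $288,206
```

Usual care accrues $229,980 in discounted lifetime costs and 6.116
QALYs per patient; surgery accrues $143,574 and 9.269 QALYs. Surgery
is therefore **dominant** — cheaper by $86,406 and more effective by
3.153 QALYs — with a net monetary benefit of $288,206 at
$64,000/QALY. The command also writes per-cycle cohort traces
(`trace_uc.csv`, `trace_surgery.csv`), the summary
(`cea_result.json`) and a reproducibility manifest.

```bash
$ mbs-cua psa --n 10000 --seed 1 --out out/psa --plot
10000 draws: 81.0% cost-saving & QALY-gaining, 96.9% below WTP, 85.1% cost-saving
```

i.e. 81% of parameter draws land in the lower-right quadrant of the CE
plane (surgery saves money *and* gains QALYs), 96.9% are good value at
the threshold, and `ce_plane.png` shows the scatter with the 95%
credible ellipse.

```bash
$ mbs-cua dsa --out out/dsa --plot      # tornado.csv + tornado.png
$ mbs-cua scenarios --out out/scn       # 8-row age x class grid
```

The tornado's widest bars are the OB3 utility weight and the pooled
OB2/OB3 management cost; every scenario in the age {30,40,50,60} ×
class {OB2,OB3} grid is dominant, with NMB decreasing in entry age.

The same functionality is available as a library:

```python
from mbs_cua import default_parameters, generate_default_lifetable, run_cohort, compare

params = default_parameters()
lt = generate_default_lifetable()
res = compare(run_cohort("UC", params, lt), run_cohort("SURGERY", params, lt), params.wtp)
print(res.icer, round(res.nmb))   # dominant 288206
```

## Layout

- `src/mbs_cua/parameters.py` — every model input, validation, config IO
- `src/mbs_cua/engine.py` — transition matrices and the cohort engine
- `src/mbs_cua/cea.py` — ICER/NMB/CE-plane statistics
- `src/mbs_cua/psa.py`, `dsa.py`, `scenarios.py` — sensitivity and scenario analyses
- `src/mbs_cua/synthetic.py` — life-table generator, fixtures, microsimulation oracle
- `src/mbs_cua/cli.py` — the `mbs-cua` command
- `docs/methods.md` — full model description, conventions and limitations
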