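# cgmkit

Analytics for continuous glucose monitor (CGM) data: a Python library
and command-line tool that computes the standard catalogue of glycemic
control and glycemic variability metrics, builds ambulatory glucose
profile (AGP) reports, and renders time-series, lasagna and
rate-of-change visualizations.

## Who this is for

CGM sensors record interstitial glucose every few minutes for days to
weeks. Clinicians and researchers summarize such traces with a large,
heterogeneous family of metrics — some are simple functionals of the
glucose distribution, others need the readings projected onto an evenly
spaced time grid aligned across days. `cgmkit` implements both families
behind one data contract: a long-format table with columns `id`
(subject), `time` (timestamp) and `gl` (glucose, mg/dL).

## What it computes

**Time-independent** (per-subject pooled values): mean, median, SD, CV,
IQR, range, MAD, quantiles; percent above/below thresholds and in
ranges (defaults 140/180/250, 54/70, [70, 180] and [63, 140] mg/dL);
eA1c = (mean + 46.7)/28.7 and GMI = 3.31 + 0.02392·mean; J-index
0.001·(mean + SD)²; M-value mean|10·log₁₀(g/r)|³; GRADE
425·(log₁₀log₁₀(g/18) + 0.16)² capped at 50, with eu-/hypo-/hyper-
glycemia attribution; the Kovatchev risk indices LBGI/HBGI from
f(g) = 1.509·((ln g)^1.084 − 5.381); Rodbard's hyperglycemia and
hypoglycemia indices and IGC; COGI; MAGE (1-SD exceedance rule, with a
moving-average-crossing variant).

**Time-dependent** (on the day-by-day grid or raw timestamps):
CONGA(n), MODD, the six Rodbard SD subtypes (SdW, SdHHMM, SdWSH, SdDM,
SdB, SdBDM), CV by day (mean and SD), ADRR, GVP, MAG, hourly-average
AUC, rate of change and its SD, and sensor active-percent.

The gridder (`day_by_day`) linearly interpolates each subject onto a
`dt0`-minute grid (inferred from the sensor period when not given),
one row per calendar day — a 5-minute sensor gives (24·60)/5 = 288
columns — refusing to bridge gaps longer than `inter_gap` (default 45
minutes) and never extrapolating beyond the observed span.

## Worked example

The bundled generator builds a five-subject panel with engineered
phenotypes (deterministic given the seed):

```python
from cgmkit import make_phenotype_panel, hyper_index, sd_roc, all_metrics

panel = make_phenotype_panel()
print(hyper_index(panel).round(3).to_string(index=False))
print(sd_roc(panel).round(3).to_string(index=False))
```

```
       id  hyper_index
Subject 1        0.377
Subject 2        4.568
Subject 3        0.897
Subject 4        2.422
Subject 5        1.961

       id  sd_roc
Subject 1   0.828
Subject 2   0.503
Subject 3   0.984
Subject 4   1.079
Subject 5   3.003
```

Subject 2 has the largest hyperglycemia index — it spends essentially
all its time above 180 mg/dL — while Subject 5 has by far the largest
SD of rate of change: large, fast swings rather than a high level.
`all_metrics(panel)` returns the full per-subject matrix (one row per
subject, 45+ metric columns):

```
       id  mean   sd   cv  above_180  in_range_70_180  gmi  conga  modd  SdW
Subject 1 129.7 29.8 23.0        7.3             92.7  6.4   20.6  22.5 27.0
Subject 2 227.4 19.9  8.8      100.0              0.0  8.7   15.0  13.0 18.5
Subject 3 149.7 35.3 23.6       17.1             82.9  6.9   26.7  28.5 33.4
Subject 4 187.7 37.4 19.9       50.4             49.6  7.8   28.3  25.2 33.8
Subject 5 164.2 62.6 38.1       35.6             60.1  7.2   60.2  53.4 60.9
```

## Command line

```sh
cgmkit simulate config.json panel.csv          # synthetic CGM CSV
cgmkit metrics panel.csv metrics.csv           # per-subject metric table
cgmkit agp panel.csv --subject "Subject 1" --out-dir report/
cgmkit plot panel.csv lasagna.png --kind lasagna --datatype average \
    --midpoint 140 --limits 60 400
```

Every subcommand uses the library defaults, logs warnings to stderr,
and writes machine-readable JSON sidecars next to report artifacts.

## Documentation

`docs/methods.md` describes the statistical conventions (sample SD,
R-type-7 quantiles, MAD scaling), the gridding and missing-data policy,
every tunable parameter with its default and units, what the synthetic
generator does and does not emulate, and known limitations.
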