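# tmtd — causal modeling and correction of reporter-ion interference in TMT proteomics

Isobaric multiplex proteomics (TMT/TMTpro) quantifies up to 18 samples per
MS2 scan through reporter-ion intensities, but co-isolated background ions
contribute a near-uniform reporter signal that compresses fold changes
toward 1 ("ratio compression"). Conventional purity metrics computed from
the MS1 isolation window (PIF, S2I, or the precursor purity fraction PPF
used here) systematically *underestimate* that interference, because
Orbitrap raw files discard sub-threshold signal: co-isolated low-abundance
peptides hide below the spectral noise cutoff yet still fragment and emit
reporter ions.

`tmtd` implements a causal regression model of the total reporter signal
of an MS2 scan that accounts for both the visible and the hidden
interference, predicts a per-PSM **estimated interference level (EIL)**,
and uses it to decompress reporter ratios and to perform
interference-balanced PTM site-to-protein normalization. It is aimed at
computational proteomics practitioners working with MS2-quantified TMT
data (MaxQuant-evidence-like PSM tables plus per-scan centroided MS1
peaks with noise values).

## The model

Per raw file (and per FAIMS compensation voltage), total reporter
intensity `Y` of each MS2 scan is modeled without intercept as

    Y ~ 0 + precursor:pepClass + nonprecursor:rawfileCharge + noiseEstimate

with

* `precursor = PIC * PPF` — the peptide ion current attributable to the
  targeted precursor. `PIC` (total peptide ion current) is the MS2 TIC
  minus the summed reporter intensities; `PPF` is the retention-time
  weighted fraction of isolation-window MS1 signal belonging to the
  precursor and its ±1 isotopes;
* `nonprecursor = PIC * (1 − PPF)` — visibly co-isolated ion current,
  interacted with the precursor charge category (charges > 3 are pooled);
* `noiseEstimate` — the hidden-ion proxy: mean noise value of the
  isolation-window peaks in the preceding MS1 scan times a run-specific
  2D kernel density of identified peptide features over (m/z, retention
  time), interpolated at the precursor coordinate;
* `pepClass` — empirical peptide classes of homogeneous fragmentation
  efficiency, grown per dataset by a greedy variance-minimizing decision
  tree over charge, TMT label count, H/R/K/E/D content and an
  extra-charge flag (leaves must hold > 100 PSMs).

Coefficients are estimated by robust IRLS with Tukey bisquare weights
(c = 4.685, MAD scale). The estimated interference level of a PSM with
regressor vector x is

    EIL = min{ 1 − x_precursorᵀ β̂_precursor / xᵀ β̂ , 1 }

Interference correction subtracts, per PSM and channel, the channel-mean
normalized intensity scaled by `min(EIL, 0.8)`, flooring results at the
spectrum-wise minimum peak intensity. Site-to-protein normalization first
*adds* uniform background to the less-interfered partner of each
site/protein pair until both share one interference level, then forms
median-scaled channel ratios.

A synthetic two-proteome benchmark generator ships as first-class code:
a constant background proteome, a spiked proteome at relative amounts
0 : 18 : 27 : 36 across four three-channel groups (design fold changes
1.5, 4/3, 2.0), one label-only channel, three spike-free channels that
read out the observed interference level (OIL) directly, and a
hidden-noise component that is present in reporter signal but absent
from the emitted MS1 peak lists.

## Worked example

```bash
tmtd simulate --seed 1 --n-psms 2000 --out-dir sim/
tmtd run --psm sim/psm.tsv --ms1 sim/ms1.tsv --layout sim/layout.json --out-dir out/
```

The driver prints per-stage progress and a row summary such as

```
{"psms": 2000, "with_eil": 2000, "corrected": 2000}
```

and writes `metrics.tsv` (ppf/tiw/pic/noise_estimate/pep_class/eil
columns appended to the PSM table), `normalized.tsv`, `corrected.tsv`,
`classes.json`, `fit.json` and `manifest.json` into `out/`. On this
simulated run the fitted per-run model in `fit.json` contains
coefficients close to the generator's planted values, e.g.

```
"precursor:pepClass=Labels<=1": 0.134,   # planted 0.14
"precursor:pepClass=Labels>1":  0.061,   # planted 0.06
"nonprecursor:charge=2":        0.083,   # planted 0.085
"nonprecursor:charge=3":        0.112,   # planted 0.11
"noiseEstimate":                78.2     # planted 80
```

(the tree's leaf labels `Labels<=1` / `Labels>1` separate the two planted
fragmentation-efficiency classes by their TMT label count, which on these
tryptic peptides is equivalent to splitting on arginine content), and the
`eil` column of `metrics.tsv` tracks the generator's true per-PSM
interference fraction to a mean absolute error of 0.006.
The same stages are available individually (`tmtd metrics`, `density`,
`classes`, `fit`, `correct`, `normalize-sites`, `eval`); library users
can drive everything from `tmtd.pipeline` and `tmtd.simulate`.

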