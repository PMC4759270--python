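# nanosip

Quantification and statistics for NanoSIMS stable-isotope-probing (SIP)
experiments on single cells — the kind of study where a foraminifer (or any
cell) is incubated with ¹⁵N/³⁴S-labeled substrates, sectioned, and imaged
with a NanoSIMS so that each organelle's isotopic enrichment can be measured
from secondary-ion count images.

**Who it is for.** Analysts holding co-registered multi-plane ion-count
stacks (¹²C¹⁴N⁻, ¹²C¹⁵N⁻, ³²S⁻, ³⁴S⁻) plus organelle-scale ROI label maps,
who need per-ROI atom% estimates with honest counting errors and
nonparametric group comparisons. Because raw NanoSIMS counts are rarely
deposited, the package also ships a ground-truth phantom generator so every
stage is testable without any instrument data.

## The core quantities

For each pixel the minor-isotope **atom fraction** is

    f = n_minor / (n_minor + n_major),      e.g.  ¹²C¹⁵N⁻ / (¹²C¹⁴N⁻ + ¹²C¹⁵N⁻)

with atom% = 100·f, counting standard error √(f(1−f)/n), and δ-notation
δ = (f/f_std − 1)·1000 ‰ against AIR (N) or VCDT (S). Processing chain:
sum ("amalgamate") the repeated raster planes; discard pixels below the
count thresholds (accumulated CN⁻ < 1000, ³²S⁻ < 60); average per-pixel
fractions over each labeled ROI (or pool the ROI's summed counts).

Groups of ROI-level atom% values are compared with a tie-corrected
**Mann–Whitney** test

    U = #{x_i > y_j} + ½·#ties,   Z = (U − nm/2) / √V,
    V = (nm/12)·[(N+1) − Σ(t³−t)/(N(N−1))],

(exact enumeration available for N ≤ 20), **Kruskal–Wallis** across k
groups, and the **Steel–Dwass** all-pairs comparison, where each pair's
standardized rank statistic t is referred to the studentized range via
q = √2·|t|, with a max-statistic permutation oracle as an independent
check of the asymptotics.

## Worked example

```python
import numpy as np
from nanosip import AIR_N, delta_from_fraction, mann_whitney

# A NanoSIMS mean of 0.3751 atom% 15N on unlabeled specimens, in delta terms:
print(delta_from_fraction(0.003751, AIR_N))   # 24.024... permil vs AIR

# Dysoxia-incubated mitochondria (n=25) were all more enriched than
# anoxia-incubated ones (n=52); with complete separation the Mann-Whitney
# statistic depends on the group sizes only:
res = mann_whitney(np.arange(1, 53), np.arange(53, 78))   # anoxic group first
print(round(res.Z, 2), res.p)                 # -7.07 1.5374597944280347e-12
```

The first number says natural specimens sit 24 ‰ above atmospheric N₂ —
the package's δ-convention is anchored to that published cross-check. The
second reproduces a published comparison: |Z| = 7.07 means the 25 dysoxic
values rank entirely above the 52 anoxic ones, p ≪ 0.001.

Longer narrative scripts live in `examples/` (δ-notation, phantom
simulation + quantification, the rank-test battery, and the full pipeline);
the `nanosip` CLI exposes the same stages as `simulate`, `quantify`,
`compare`, `report` and `demo` subcommands:

```bash
nanosip demo --seed 0 --out-dir scratch/demo
```

writes per-field TIFF sessions, ROI/summary/comparison CSVs, Steel–Dwass
tables, scatter reports and a run manifest, and prints the per-class
dysoxic-vs-anoxic Mann–Whitney table.

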