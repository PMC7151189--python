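# distscreen

Screening multiple-choice items for **ability-related distractor
discrimination** — deciding, from a small pilot sample and raw
number-correct scores, whether an item's *wrong* options still separate
test-takers by ability and the item is therefore a candidate for nested
logit (2PNL) scaling.

Test developers who want the extra measurement precision that nested logit
models offer at the low-ability end face a chicken-and-egg problem: those
models need far more data than a pilot study provides, so items must be
pre-selected with simple descriptive statistics.  `distscreen` implements
the two item-level effect sizes built for exactly that decision, the
classical per-distractor indices used as companions, the 2PNL response
simulator, and the Monte-Carlo harness that calibrates the screening
thresholds.

## The statistics

For an item with K retained distractors (retention = chosen by ≥ 5% of all
participants), computed over the item's non-solvers:

* **Cohen's ω_G** = √(χ²/n), with χ² the Pearson statistic of the
  K × G table of distractor choice against G score-quantile ability
  groups (G = 2 and 5).  An interaction between ability group and
  distractor choice — the signature of discriminating distractors — makes
  ω_G large.
* **R_CC**, the canonical correlation between K−1 distractor-choice
  indicator variables and the non-solvers' total scores; identical to the
  correlation ratio η of the one-way distractor-group layout.
* Companions: point-biserials **PB_D** (choosers of D vs. everyone) and
  **PB_DC** (choosers of D vs. solvers), the Haladyna–Downing uniformity
  effect size **ω_D**, and Goodman–Kruskal's **γ** for rising selection
  ratios (odds of solving vs. choosing D increasing with ability).

Decision rules calibrated by the simulation study: flag an item when
R_CC (or ω_2) exceeds **0.30**, require type-I error ≤ 0.05 under
zero-discrimination distractors, and treat mean γ > 0.30 /
mean PB_DC < −0.30 as boundary conditions for well-behaved items.

The data-generating model behind the simulator and the study design are
described in [docs/methods.md](docs/methods.md).

## Worked example

Simulate the package's discriminating illustration dataset (N = 10,000,
ten difficult items, three distractors, moderate 2PL discrimination, high
NRM distractor slopes λ = (−1, 0, 1)) and analyse it:

```python
import numpy as np
from distscreen import analyze_all_items
from distscreen.distractor_stats import item_report_frame
from distscreen.nested_logit_sim import example_item_bank, simulate_scored

rng = np.random.default_rng([0, 1])
bank = example_item_bank("high", rng)
scored = simulate_scored(bank, 10_000, rng)
print(item_report_frame(analyze_all_items(scored)).round(3).head(4))
```

```
item  n_nonsolvers  n_below_5pct  r_cc  omega_2  omega_5  mean_pb_dc  mean_gamma
  i1          6844             0 0.375    0.320    0.367      -0.460       0.881
  i2          7024             0 0.356    0.315    0.355      -0.489       0.926
  i3          6844             0 0.403    0.344    0.392      -0.480       0.926
  i4          6651             0 0.377    0.322    0.371      -0.474       0.852
```

Every item clears the R_CC > 0.30 flag — the distractors carry ability
information.  Rerunning with `example_item_bank("zero", ...)` (no
distractor discrimination) drops R_CC and ω_G to ≈ 0.01–0.03 while the
solution-focused companions (mean PB_DC, mean γ) barely move: the two
families of statistics measure different things.

The same pipeline is available from the shell:

```bash
distscreen simulate --n 500 --items 10 --distractors 7 \
    --difficulty difficult --discrimination moderate --nrm very_high \
    --seed 7 --out sim/
distscreen analyze sim/responses.csv sim/key.csv --out report/
distscreen study --cells typeI --reps 100 --seed 1 --out study/
distscreen fixtures --seed 0 --out examples/
```

`analyze` writes a per-item report (`items.csv`, with the R_CC flag), a
per-distractor report and trace-line tables; `study` runs design cells of
the Monte-Carlo study and writes per-cell records plus type-I/power/
substance summaries.

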