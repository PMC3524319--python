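# primescreen

Detection and mechanistic classification of cellular **priming** — the
amplified response of a cell to a high-dose stimulus after pretreatment
with a sub-threshold low dose of the same stimulus, as seen in
IFN-γ- and endotoxin-treated macrophages.

The package implements one operational definition of priming at three
levels of description:

- **`primescreen.features` / `primescreen.trinode`** — a generic
  three-node ODE motif (stimulus S → regulators x₁, x₂ → readout x₃,
  activities in reduced units on [0, 1]) with a two-stage annealed
  search for kinetics that satisfy the priming definition, and a
  classifier that assigns primed systems to three mechanisms:
  *Pathway Synergy* (PS), *Activator Induction* (AI) and
  *Suppressor Deactivation* (SD).
- **`primescreen.expression` / `primescreen.motifs`** — a time-course
  expression screening pipeline for the six-condition design (Control,
  LD, HD 3 h/24 h, LD+HD 3 h/24 h with replicate pools): detection-call
  and 2-fold filters, Welch's t-test with Benjamini–Hochberg correction
  at p < 0.05, gene grouping (LD-induced/-reduced, early/late/persistent
  dynamics), readout identification, mechanism roles, dynamics
  reshuffling between the HD and LD+HD arms — and a matcher that maps
  role-annotated genes onto signed regulatory networks to emit candidate
  PS/AI/SD priming motifs.
- **`primescreen.jakstat`** — a detailed IFN-γ Jak/STAT signaling model
  (36 species, 50 parameters; mass action plus Michaelis–Menten
  transcription) under the prime–wash–restimulate protocol
  (0.15 µg/L × 72 h, 10-min wash, 5 µg/L × 48 h), with total STAT1,
  total SOCS1, phospho-STAT1 dimer (STAT1\*D) and IRF-1 as readouts.

A synthetic-data generator (`primescreen.synth`) emulates the
six-condition microarray design (≈12,000 probes, 3 pools, planted gene
classes with multiplicative log-normal noise) and plants signed networks
with recoverable motifs, so the whole pipeline is testable offline.

## The priming definition

A readout x₃ shows priming when, against the untreated baseline,

1. the low dose alone does not activate it (max x₃ < 0.1 in reduced
   units with 1 the maximal induction),
2. the high dose alone does activate it, and
3. the sequential low-then-high protocol drives it at least **50 %
   higher** than the high dose alone.

Primed systems classify by the regulator features Δss xᵢ (level change
at the end of the LD period) and the Δmax difference (HD-window maximum
with vs without pretreatment), against a resolution cutoff δ = 0.1:
Δss x₁ < −δ → SD; Δss x₂ > δ with Δmax difference > δ → PS, within
±δ → AI.

## Worked example

```python
from primescreen.synth import SyntheticSpec, generate_expression
from primescreen.expression import run_screen

mat, truth = generate_expression(SyntheticSpec(seed=0))
summary = run_screen(mat)
print(summary.counts())
```

prints

```
{'n_input_probes': 12000, 'n_detected': 11400, 'n_nontrivial': 205,
 'n_ld_induced': 26, 'n_ld_reduced': 20, 'n_hd_early': 78,
 'n_hd_late': 40, 'n_hd_persistent': 48, 'n_ldhd_early': 82,
 'n_readout_relaxed': 27, 'n_readout_strict': 27,
 'n_early_to_late_or_persistent': 5, 'n_late_to_early_or_persistent': 17}
```

— of 12,000 probes, 11,400 carry a Present call, 205 show non-trivial
dynamics (a significant ≥ 2-fold change in at least one condition);
26 of the 27 planted LD-induced and all 20 LD-reduced genes are
recovered (candidate priming regulators), 78 genes respond early under
HD versus 82 under LD+HD, and the pretreatment moves 5 early-responders
into the late/persistent groups and 17 late-responders the other way —
the dynamics-reprogramming signature of priming.

The detailed signaling model tells the mechanistic story
(`python analysis/04_jakstat_protocol.py`):

```
STAT1sD: peak above baseline  LD 8.11e-05  HD 0.0748  LD+HD 0.204  -> primed/HD ratio 2.72 (primed: True)
IRF1:    peak above baseline  LD 0.0389    HD 10.1    LD+HD 30.7   -> primed/HD ratio 3.04 (primed: True)
```

The low dose quietly quadruples the STAT1 pool (without turning on the
SOCS1 brake); on restimulation the enlarged pool feeds a phosphorylation
burst that beats the SOCS1 shutdown — a combined AI/PS mechanism.

## Analysis scripts

Numbered drivers under `analysis/` reproduce the main computations and
write tables/figures under `results/`:

| script | what it does |
| --- | --- |
| `01_search_priming_motifs.py` | annealed search of the three-node model; mechanism-region scatter + Δmax histograms |
| `02_screen_expression.py` | screening pipeline on the emulated design, recovery vs ground truth |
| `03_match_motifs.py` | role genes → signed network → PS/AI/SD motif table |
| `04_jakstat_protocol.py` | Jak/STAT protocol simulation, readout trajectories + priming report |

A `primescreen` command-line interface wraps the same steps
(`primescreen synth`, `primescreen trinode search`,
`primescreen expr screen`, `primescreen motifs find`,
`primescreen jakstat run`, `primescreen report`); see `--help`.

## Documentation

`docs/methods.md` describes the models, the search, the screening rules,
the synthetic-data assumptions and the numerical choices in detail.
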