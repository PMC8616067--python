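# emgcycle

Muscle-synergy analysis of cyclic surface-EMG recordings — built for
studying how muscle coordination changes when the force demand of a cyclic
task (e.g. pedaling against increasing resistance) is modulated, and for
validating every analysis stage against synthetic signals with planted
ground truth.

## Who this is for

Movement scientists and biomedical engineers who record multi-channel
surface EMG (sEMG) during cyclic tasks and want a tested, scriptable
pipeline from raw signals to phase-level statistics: linear envelopes,
kinematics-free cycle segmentation, anchor-aligned cycle averaging,
non-negative matrix factorization (NMF) into motion phases, and
nonparametric comparisons across task conditions.

## The model

The standardized envelope matrix `M` (muscles × time, non-negative) is
factorized as

```
M ≈ W × H,    W ∈ R+^{m×n},  H ∈ R+^{n×t}
```

where each column of `W` holds the muscle weighting of one motion phase and
the corresponding row of `H` its temporal activation.  Model quality is the
global variance accounted for,

```
VAF = 1 − ‖M − WH‖²_F / ‖M‖²_F ,
```

and the model order is the smallest `n` whose best-of-restarts VAF reaches
a threshold (0.95 by default; `n = 3` is the expected order for pedaling —
traction, power initiation, power end).  From a fitted model the package
computes:

* **relative phase contribution**
  `C_i = (Σ_m W_mi)(Σ_t H_i(t)) / Σ_j (Σ_m W_mj)(Σ_t H_j(t))` — the
  fraction of total reconstructed signal amplitude generated by phase `i`;
* **temporal / spatial stability indices** — the mean zero-lag correlation
  coefficient, over all pairs of motion cycles, between per-cycle temporal
  patterns (`H` rows) or muscle weightings (`W` columns), each in [−1, 1];
* **pairwise Mann–Whitney U tests** of any metric across condition levels
  (exact null for small tie-free samples, tie-corrected normal
  approximation otherwise).

The synthetic generator plants a known `W`, per-cycle burst timing, and
cycle boundaries in amplitude-modulated band-limited carrier noise, so all
of the above can be verified by parameter recovery.

## Worked example

```
emgcycle simulate --out sim --seed 123        # 4 resistance levels x 3 trials
emgcycle analyze --in sim --out out
emgcycle report --in out
```

`out/models.csv` then contains, for this seed:

```
 condition  selected_order      vaf  n_cycles
         2               3 0.994765        36
         3               3 0.994527        36
         4               3 0.996312        36
         5               3 0.997951        36
```

Each condition's 36 time-normalized cycles are explained at better than 99%
VAF by three phases.  The median relative contributions
(`out/report/contribution_summary.csv`) shift with resistance level:

```
phase          1      2      3
condition
2          0.310  0.317  0.380
3          0.295  0.320  0.388
4          0.275  0.335  0.385
5          0.261  0.355  0.384
```

— the early-power phase (phase 2, knee-extensor dominated) grows at the
expense of the traction phase as resistance rises, and
`out/comparisons.csv` flags those shifts (e.g. contribution of phase 2,
level 2 vs 5: `U = 239, p = 4.2e-06, *`).  The per-trial stability indices
(`out/report/stability_summary.csv`) increase with level, e.g. median
temporal stability of phase 1 rises from 0.879 (level 2) to 0.972
(level 5) — higher force, more reproducible cycles, exactly the planted
effect.

The same machinery is available as a library; see the API in
`emgcycle/__init__.py` (`generate_trial`, `preprocess`,
`detect_boundaries`, `normalize_cycles`, `nmf`, `select_order`,
`relative_contribution`, `per_cycle_models`, `mann_whitney_u`, ...).

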