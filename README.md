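# unspool

Free-energy estimation machinery for DNA-unwrapping-style problems, built
and validated on synthetic systems with exactly known answers.

Partially unwrapping the DNA from a nucleosome (or, generally, a polymer
from a spool it is bound to at discrete sites) is naturally described by a
free-energy profile along the end-to-end distance *d* of the polymer, or
along the number of unwrapped units *R₂*.  Computing such profiles from
simulation takes an enhanced-sampling protocol; `unspool` implements the
full chain as a reusable, tested library:

1. **Multi-walker adaptive biasing ("flooding")** — many concurrent
   walkers share one history-dependent biasing potential *U*(d) tabulated
   on a grid (resolution Δd, default 1 Å).  Each walker deposits a
   Gaussian kernel of integrated weight k\_BT·dt/τ at its current *d*
   every step (flooding time τ, default 100 ps), destabilizing visited
   regions until −*U*(d) approximates the free energy and the per-interval
   deposited energy becomes spatially uniform — the convergence
   diagnostic.  One-sided harmonic walls k\_w(d−d\_wall)² confine the
   walkers to the range of interest.
2. **Umbrella sampling** — windows on an inclusive grid of centers
   d\_i = lo + 2 Å·i, each restrained by the combined bias
   V\_i(d) = k\_i (d − d\_i)² + U\_abmd(d) (note: no ½ factor), with the
   frozen final flooding bias shared bit-identically across windows.
   Window seeds are the walkers whose *d* lies closest to each center.
3. **WHAM** — the unbiased distribution P(d) and per-window shifts F\_j
   are obtained by iterating

       P(x) ∝ Σᵢ Hᵢ(x) / Σⱼ nⱼ exp([Fⱼ − Vⱼ(x)]/k_BT)
       Fⱼ   = −k_BT ln Σₓ P(x) exp(−Vⱼ(x)/k_BT)

   to self-consistency (tolerance 10⁻⁸ kcal/mol on max|ΔFⱼ|), in log
   space, giving F(d) = −k_BT ln P(d) and per-sample unbiased weights.
4. **Reweighting** — the weighted ensemble is projected onto structural
   coordinates: F(R₂) along the unwrapped-unit count, per-bin observable
   means Ā(R₂) and spreads σ(R₂), and 2-D landscapes F(d, R₂).
5. **Structural metrics** — unwrapped-unit counting (center displaced
   outward by more than 4 Å from the wrapped reference), residue contact
   probabilities (any atom pair within 4 Å, inclusive), end-asymmetry
   distributions normalized per total count, and stitching of
   free-energy changes across protocol stages.

Because real trajectories of this kind are expensive and typically not
deposited, the package ships its own ground-truth systems
(`unspool.toy_systems`): 1-D analytic potentials whose free energy is the
potential itself, and a coarse **bead-on-spool mimic** — two
mirror-symmetric arms of beads, bound at discrete core sites with tunable
energies ε and forced to unwrap outside-in by a gating bond — whose
count distribution is exactly computable by transfer-integral enumeration.
Every estimator in the pipeline is validated against these oracles.

## Worked example

Recover a double-well landscape (barrier 3 kcal/mol, wells at 3 and 7 Å)
from 21 umbrella windows of 20 000 exactly drawn samples each:

```python
>>> from unspool.benchmarks import wham_recovery_benchmark
>>> r = wham_recovery_benchmark(seed=1)
>>> print(f"RMSD(recovered - analytic) = {r.rmsd:.4f} kcal/mol over {r.n_samples} samples")
RMSD(recovered - analytic) = 0.0164 kcal/mol over 420000 samples
```

The RMSD is measured over the well-to-well range after mean alignment;
0.016 kcal/mol is far below thermal noise (k\_BT ≈ 0.596 kcal/mol at
300 K), i.e. the estimator reproduces the landscape essentially exactly.

The mimic's exact free energy along the per-end unwrapped count shows the
staircase produced by its four ε = 1 kcal/mol binding sites (flat between
sites, one ε per release):

```python
>>> import numpy as np
>>> from unspool.toy_systems import SpoolMimicSpec, free_energy_vs_count
>>> print(np.round(free_energy_vs_count(SpoolMimicSpec(), per_end=True).f, 3))
[0.    0.944 0.976 1.016 2.006 2.037 2.077 3.068 3.098 3.138 4.145]
```

A two-stage protocol runs end-to-end from the command line (the second
stage models the hand-off after partial unwrapping: two outermost beads
of each arm removed):

```
$ unspool run-all examples/mimic_demo_stage1.toml examples/mimic_demo_stage2.toml --out demo_out
{
  "stitched_total_kcal_mol": 5.549340358321301,
  "stages": [
    {"stage_id": "stage1", "delta_f_kcal_mol": 4.012151424948402, "arm_length": 4},
    {"stage_id": "stage2", "delta_f_kcal_mol": 1.537188933372898, "arm_length": 2}
  ]
}
```

Each stage directory contains the bias grid, walker traces, window
samples, WHAM profile and convergence report, the F(R₂) and 2-D
landscapes, the asymmetry matrix and a manifest with checksums; single
phases are available as `unspool simulate-abmd / run-umbrella / wham /
reweight / metrics`.

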