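# ddrensemble

Ensemble modelling of weakly ordered protein domains from spin-label
distance-distribution restraints.

Intrinsically disordered domains (IDDs) are not necessarily structureless:
their conformational ensembles can deviate *weakly* from a random coil —
some chain sections are systematically more compact or more extended than
coil statistics predict. Pulsed dipolar EPR spectroscopy (DEER) on pairs of
nitroxide spin labels measures the full *distribution* P(r) of label-label
distances in the 15-80 Å range, not just a mean, which makes such weak
deviations detectable. `ddrensemble` implements the complete workflow:

1. **Trace inversion** (`ddrensemble.deer`) — the dipolar evolution signal
   is modelled with a multi-pathway kernel

       K(t,r) = [Λ₀ + λ₁K₀(t,r) + λ₂K₀(t−T₀₂,r)] · e^(−k(λ₁|t|+λ₂|t−T₀₂|))

   with K₀ the elementary powder-averaged dipolar kernel
   (ν_dd = 52.04 MHz·(r/nm)⁻³). Inversion to P(r) is ill-posed and is done
   by parametric fitting (single Gaussian, SAW-ν, multi-Gaussian with
   AIC/BIC component selection) or Tikhonov regularization with
   nonnegativity (α fixed, or chosen by AIC/BIC/discrepancy).
2. **Restrained conformer sampling** (`ddrensemble.sampler`) — backbone
   chains are grown residue-by-residue from residue-specific coil
   Ramachandran statistics with ideal geometry and CA-level self-avoidance.
   Each Gaussian restraint (⟨r⟩, √2·σ_r) is scored as soon as both sites
   have coordinates; a conformer is abandoned early when the product of
   restraint scores drops below 0.75. Chains can be tethered to a folded
   domain supplied as a (multi-model) PDB anchor.
3. **Population fitting** (`ddrensemble.ensemble_fit`) — conformer
   populations p are refined on the probability simplex to maximize the
   geometric mean over restraints of the overlap

       o_m = Σ_r min{P_pred(r), P_exp(r)},   ō = (∏ o_m)^{1/M}

   with block-iterative conformer admission, adaptive block growth and
   1%-of-maximum population pruning. The objective is concave, so the
   projected-gradient solver finds the global optimum.
4. **Weak-order analytics** (`ddrensemble.analysis`) — segment-wise RMS
   CA-CA distances R_k, the power-law fit b·k^ν, the segment-length
   deviation matrix ΔL_ij (deviation of each pair's RMS distance from the
   mean at the same separation k), the ensemble width Γ (population-weighted
   RMS pairwise CA RMSD after Kabsch superposition), and radii of gyration.
5. **Jack-knife validation** (`ddrensemble.jackknife`) — leave-one-restraint-out
   re-modelling: each omitted distribution is predicted from an ensemble
   fitted to the remaining restraints; inconsistent restraints are flagged
   (overlap below median − 2·MAD), and the merged "super-ensemble" of all
   leave-one-out runs provides an enlarged basis for a final, improved fit.
6. **Synthetic ground truth** (`ddrensemble.synthetic`) — freely jointed
   chains, segment-compacted and two-state weakly ordered ensembles,
   simulated restraints and noisy DEER traces, so every stage is testable
   end to end with known answers.

## Worked example

Reference-state check on the 100-residue section of the FUS N-terminal
low-complexity domain (a fully disordered reference system):

```python
import numpy as np
import ddrensemble as dd
from ddrensemble.sequences import FUS_1_100

ens = dd.build_raw_ensemble(FUS_1_100, n_target=1000, rng_seed=2)
fit = dd.fit_scaling_law(dd.segment_rms(ens))
print(f"R_k = {fit.b:.2f} * k^{fit.nu:.2f} A")

ca = ens.ca_stack()
d = np.linalg.norm(ca[:, 28] - ca[:, 9], axis=1)      # section 10-29
print(f"CA 10-29: mean {d.mean():.1f} A, sigma {d.std():.1f} A")

lab = dd.label_distance_distribution(ens, 10, 29, dd.default_grid(0.5, 120, 0.5))
print(f"label 10-29: mean {lab.mean():.1f} A, sigma {lab.std():.1f} A")
```

prints (seed 2):

```
R_k = 5.52 * k^0.55 A
CA 10-29: mean 26.9 A, sigma 8.9 A
label 10-29: mean 29.6 A, sigma 11.7 A
```

i.e. the unrestrained coil ensemble follows the Flory-type scaling law
with ν ≈ 0.55 and Kuhn-like prefactor ≈ 5.4 Å, and attaching the label
surrogate shifts the 20-residue section distribution up by ≈ 2.7 Å and
broadens it by ≈ 32% — the expected rotamer-convolution effect.

The same pipeline from the shell:

```bash
ddrensemble synth --seed 3 --out fixtures/            # ground truth + restraints
ddrensemble fit --ensemble fixtures/truth.pdb \
    --populations fixtures/truth.pop \
    --restraints fixtures/restraints.txt --out fit/   # population fitting
ddrensemble analyze --ensemble fit/fit.pdb \
    --populations fit/fit.pop --out report/           # nu, b, Gamma, R_g
```

Each subcommand writes a `report.json` with input hashes, the seed and
the key scalars.

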