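# neuroforward

Forward modeling of local field potentials (LFP) and magnetoencephalographic
(MEG) signals from population models of cortical activity — both spiking
networks of adaptive exponential integrate-and-fire (AdEx) neurons and their
mean-field (population-rate) reduction.

Mean-field models make whole-brain simulation tractable, but they do not by
themselves produce the signals experimentalists record. `neuroforward`
implements the missing forward models and validates them on slow-wave
(up/down state) activity, where the spiking network and its mean-field
reduction can be compared signal by signal:

* **LFP** via unitary-LFP kernels: every presynaptic spike contributes a
  Gaussian template `K(x, t) = A0(z) exp(−r/λ) exp(−(t−t_p)²/2σ²)` with peak
  time `t_p = t0 + d + r/v_a`. For rate models the spike sum is replaced by
  the population flux `n_p ν_p(t)` convolved with the disk-averaged kernel
  `≈ 0.3 A0(z)` (the mean of the radial decay over a disk of radius `2λ`).
* **MEG** via a current-dipole / volume-conductor model: the primary dipole
  is the population axial current of two-compartment pyramidal cells,
  `Q_s = n_e L I_A` with `I_A = g_A (V_D − V_S)`, the secondary dipole comes
  from return currents across conductivity interfaces,
  `Q_c = −Σᵢ (σ′ᵢ−σ″ᵢ) ∮ Φ dSᵢ`, with Φ supplied by the kernel LFP; fields
  follow the quasi-static far-field formula `B = (μ0/4π) Q×r/|r|³`.
* **Up/down-state statistics**: state onsets/offsets at 3 SD of the
  base-state fluctuation from baseline; amplitudes and durations per state.
* **Whole-brain mode**: many mean-field nodes coupled through a weighted,
  delayed (synthetic) connectome, with per-region LFP and a diagonal
  gain-matrix MEG.

See `docs/methods.md` for model details, assumptions and limitations.

## Worked example

Simulate the mean-field slow-wave limit cycle, synthesize the surface LFP
and summarize its up states:

```python
from neuroforward.config import load_and_validate_config
from neuroforward.pipeline import lfp_meanfield_experiment

cfg = load_and_validate_config()       # shipped slow-wave study conditions
result, trace, lfp = lfp_meanfield_experiment(cfg, seed=3)
print(result.to_dict())
```

```
{'name': 'lfp_meanfield', 'n_states': 43, 'amplitude_uV': 208.91,
 'amplitude_sd_uV': 14.47, 'duration_s': 0.576, 'duration_sd_s': 0.165}
```

43 up states were detected in 30 s of activity: slow waves at ~1.4 Hz whose
surface-LFP deflections average ~209 µV relative to the near-silent
down-state baseline and last ~0.58 s between the 3-SD crossings. The spiking-network
counterpart (`lfp_spiking_experiment`) runs the 10,000-neuron AdEx network
with the same kernel table and yields statistically compatible up states —
the package's central validation.

The same applies to the magnetic field:

```python
from neuroforward.pipeline import meg_meanfield_experiment
result, _, ts = meg_meanfield_experiment(cfg, seed=3, trace=trace)
```

`ts` carries the primary (axial-current) and secondary (volume-conduction)
dipoles and their fields separately; with the shipped geometry the conduction
term contributes about a tenth of the total, i.e., the MEG is dominated by
neuronal axial currents.

Command-line equivalents:

```bash
neuroforward simulate-meanfield --out mf.h5 --seed 3
neuroforward lfp --rates mf.csv --out lfp.h5
neuroforward meg --trace mf.csv --out meg.h5
neuroforward states --in lfp.h5 --k-sd 3 --out states.json
neuroforward simulate-brain --synthetic 68 --out brain.h5
neuroforward reproduce-paper --out report/ --seed 3
```

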