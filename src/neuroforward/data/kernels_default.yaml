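# Unitary-LFP kernel parameters per presynaptic cell type.
#
# Provenance: the temporal constants (sigma, d) and spatial constants
# (lambda, va) follow the experimentally derived human uLFP Gaussian
# templates (axonal speed 200 mm/s, radial space constant 200-250 um,
# widths of a few ms, ~10 ms constant delay). The depth-amplitude table
# A0(z) is a REPRESENTATIVE (synthetic) transcription, not a verbatim copy
# of the published table: it preserves the published structure -- inhibitory
# somatic peak of a few microvolts, weaker excitatory amplitudes of opposite
# polarity, and a dipolar sign flip between soma level and cortical
# surface -- with magnitudes calibrated once so that the shipped slow-wave
# configurations reproduce the reference up-state LFP amplitudes.
# Replace this block with measured values when available.
#
# Depths: deep = -400 um, soma = 0, superficial = +400 um, surface = +800 um.
excitatory:
  A0_uV:
    deep: -0.254
    soma: -0.798
    superficial: 0.290
    surface: 0.725
  lambda_um: 200.0
  sigma_ms: 3.15
  d_ms: 10.4
  va_mm_per_s: 200.0
inhibitory:
  A0_uV:
    deep: 0.363
    soma: 2.176
    superficial: 0.145
    surface: -0.218
  lambda_um: 200.0
  sigma_ms: 2.1
  d_ms: 10.4
  va_mm_per_s: 200.0
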