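provenance: fitted by neuroforward.adex_meanfield.fit_transfer_function from single-neuron
  AdEx simulations under Poisson bombardment
excitatory:
  P_mV:
  - -49.03211480877263
  - 1.0401808112118658
  - 2.9559708549544217
  - -3.4654307598411958
  - 1.135198144186835
  - 5.9797077774808685
  - 2.4451095712467623
  - -1.679655031163408
  - 1.5033931684965067
  - 4.853192284271053
  meta:
    K_e: 400.0
    K_i: 100.0
    n_grid_points: 1224
    n_fit_points: 291
    fit_rms_Hz: 3.3225170067740724
    duration_ms: 10000.0
    seed: 10
    nu_e_grid_Hz:
    - 0.1
    - 0.2
    - 0.35
    - 0.5
    - 0.75
    - 1.0
    - 1.5
    - 2.0
    - 3.0
    - 4.0
    - 6.0
    - 8.0
    - 12.0
    - 16.0
    - 24.0
    - 36.0
    - 50.0
    nu_i_grid_Hz:
    - 0.0
    - 0.5
    - 1.0
    - 2.0
    - 4.0
    - 8.0
    - 12.0
    - 18.0
    - 26.0
    - 36.0
    - 50.0
    - 70.0
    W_grid_pA:
    - 0.0
    - 30.0
    - 60.0
    - 120.0
    - 240.0
    - 480.0
inhibitory:
  P_mV:
  - -50.63629073312105
  - 1.3428714423002137
  - 4.1155508865792605
  - -1.918495113312068
  - 0.7652712424748449
  - 0.44601335624942756
  - 3.484000828637134
  - -1.8280673889447985
  - 2.012062890237734
  - 2.625473087976472
  meta:
    K_e: 400.0
    K_i: 100.0
    n_grid_points: 204
    n_fit_points: 48
    fit_rms_Hz: 0.8766138368676932
    duration_ms: 10000.0
    seed: 11
    nu_e_grid_Hz:
    - 0.1
    - 0.2
    - 0.35
    - 0.5
    - 0.75
    - 1.0
    - 1.5
    - 2.0
    - 3.0
    - 4.0
    - 6.0
    - 8.0
    - 12.0
    - 16.0
    - 24.0
    - 36.0
    - 50.0
    nu_i_grid_Hz:
    - 0.0
    - 0.5
    - 1.0
    - 2.0
    - 4.0
    - 8.0
    - 12.0
    - 18.0
    - 26.0
    - 36.0
    - 50.0
    - 70.0
    W_grid_pA:
    - 0.0
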