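# Synthetic placeholder parameters for the Usman et al. model.
name: Usman
CL: "max(0.5, 3.5 - 0.015*age)"
V: "0.65*weight"
omega_cl: 0.11
omega_v: 0.05
error:
  type: proportional
  sigma_prop: 0.21
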