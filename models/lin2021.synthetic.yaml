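# Synthetic placeholder parameters for the Lin et al. (2021) model.
name: Lin2021
CL: "0.03*crcl_cg + 1.0"
V: "0.75*weight"
omega_cl: 0.08
omega_v: 0.04
error:
  type: proportional
  sigma_prop: 0.18
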