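# Synthetic placeholder parameters for the Munir et al. model.
name: Munir
CL: "0.042*crcl_cg"
V: "45 + 0.3*weight"
omega_cl: 0.10
omega_v: 0.05
error:
  type: proportional
  sigma_prop: 0.19
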