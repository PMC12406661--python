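# Synthetic placeholder parameters for the Zhou et al. one-compartment model.
# Edit the numeric values below with the published estimates from the original
# publication before clinical use; the shipped values are plausible stand-ins
# so the registry loads and the pipeline is exercisable end-to-end.
name: Zhou
CL: "0.05*crcl_cg + 0.3"
V: "0.8*weight"
omega_cl: 0.09
omega_v: 0.04
error:
  type: proportional
  sigma_prop: 0.20
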