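# Synthetic placeholder parameters for the Staatz et al. model (developed in
# a population with relatively high serum creatinine). Edit with published
# estimates from the original publication.
name: Staatz
CL: "0.034*crcl_cg + 0.4"
V: "1.0*weight"
omega_cl: 0.12
omega_v: 0.06
error:
  type: combined
  sigma_prop: 0.15
  sigma_add: 1.0
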