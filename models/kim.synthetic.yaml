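# Synthetic placeholder parameters for the Kim et al. (all patients) model.
# The volume term distinguishes early (<=72 h) from later treatment, the
# structural feature this model is known for. Edit with published estimates.
name: Kim
CL: "0.045*crcl_cg + 0.5"
V: "(0.9 if treatment_day <= 3 else 0.7)*weight"
omega_cl: 0.10
omega_v: 0.05
error:
  type: proportional
  sigma_prop: 0.22
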