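name,dg_kcal_mol,error_kcal_mol,time_ns
c_site,-35.2,1.6,445
Theta_site,-0.2,0.0,14
Phi_site,-0.1,0.0,10
Psi_site,-0.1,0.0,10
theta_site,-0.2,0.0,18
phi_site,-0.1,0.0,14
separation_term,-12.0,0.6,245
c_bulk,26.8,1.2,215
o_bulk,7.9,,
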