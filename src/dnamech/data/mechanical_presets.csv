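# Published mechanical and thermodynamic parameters for the nine DNA-like polymers.
# DNA 1 is natural DNA; 2-9 carry base analogs. P_manning_nm is a theoretical
# charge-stiffness prediction retained as a reference constant only (no computation).
label,Tm_C,Tm_sd_C,P_nm,P_sd_nm,P_manning_nm,gamma0_bp_per_turn,gamma0_sd,C_1e19_erg_cm,C_sd_1e19,Pt_nm,Pt_sd_nm
DNA1,87.1,0.5,51.5,0.2,51.5,10.52,0.01,2.27,0.11,55.7,2.6
DNA2,85.3,0.6,45.4,0.4,,10.47,0.01,2.30,0.13,56.5,3.1
DNA3,93.3,0.7,42.9,0.3,,10.62,0.01,3.07,0.19,75.4,4.7
DNA4,91.5,0.7,44.3,0.1,38.1,10.62,0.01,1.48,0.05,36.4,1.2
DNA5,88.3,0.3,41.8,0.1,,10.69,0.01,0.85,0.04,20.9,1.0
DNA6,86.5,0.7,41.8,0.1,64.6,10.51,0.02,0.61,0.03,14.9,0.8
DNA7,93.4,0.3,50.3,0.1,,10.64,0.01,1.09,0.07,26.8,1.6
DNA8,86.8,0.4,58.5,0.2,58.1,10.57,0.01,1.08,0.08,26.5,1.9
DNA9,93.0,0.5,49.5,0.2,,10.58,0.01,3.24,0.07,79.6,1.8
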