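# Published cyclization J-factors (nM) and ligation rate constants for the nine
# DNA-like polymers, by fragment length. J = k_C1 / k_D.
label,n_bp,J_nM,J_sd_nM,kC1_1e4_per_s,kC1_sd_1e4_per_s,kD_1e4_per_nM_s,kD_sd_1e4_per_nM_s
DNA1,201,2.2,0.2,13.9,5.6,6.5,3.1
DNA1,202,1.5,0.3,12.9,4.8,9.2,4.4
DNA1,203,0.5,0.1,5.3,1.8,10.9,4.5
DNA1,204,0.3,0.1,3.5,1.5,10.9,5.0
DNA1,205,0.1,0.1,2.1,1.2,15.3,7.0
DNA1,206,0.3,0.1,8.8,1.3,26.6,5.1
DNA1,207,0.6,0.1,5.7,0.7,9.6,1.5
DNA1,208,1.2,0.2,11.5,2.0,9.7,3.3
DNA1,209,2.6,0.7,24.2,5.0,9.7,3.1
DNA1,210,3.4,0.2,50.9,9.8,14.9,2.4
DNA1,211,5.0,1.5,48.3,9.1,10.4,3.5
DNA2,201,6.0,0.9,13.3,1.8,2.3,0.4
DNA2,203,1.2,0.1,2.4,0.2,2.1,0.2
DNA2,205,0.8,0.3,1.9,0.8,2.4,0.7
DNA2,207,5.6,1.3,12.2,4.5,2.1,0.5
DNA2,209,14.7,4.6,24.7,8.7,1.7,0.2
DNA2,211,9.1,1.5,20.7,6.0,2.3,0.7
DNA3,201,17.6,4.1,22.2,8.3,1.3,0.3
DNA3,203,17.1,2.4,25.4,9.2,1.5,0.4
DNA3,205,4.2,0.7,9.6,5.8,2.4,1.7
DNA3,207,0.4,0.3,0.9,0.4,2.1,0.3
DNA3,209,3.4,0.9,5.6,2.9,1.7,1.1
DNA3,211,18.3,3.8,31.0,7.2,1.7,0.1
DNA4,201,10.1,2.1,21.1,4.0,2.2,0.8
DNA4,203,9.7,0.5,16.6,4.2,1.7,0.5
DNA4,205,4.2,1.8,11.0,4.0,2.7,0.4
DNA4,207,2.3,0.2,7.0,3.2,3.0,1.0
DNA4,209,5.1,0.6,12.4,5.3,2.4,0.8
DNA4,211,12.3,0.9,23.2,4.1,1.9,0.3
DNA5,201,2.3,0.3,403,31,177,15
DNA5,203,2.4,0.2,443,54,188,24
DNA5,205,1.5,0.1,238,23,163,17
DNA5,207,1.0,0.1,171,36,173,17
DNA5,209,1.4,0.1,229,36,165,16
DNA5,211,2.6,0.5,486,64,190,26
DNA6,201,0.29,0.02,119,12,402,24
DNA6,203,0.24,0.03,92,25,384,66
DNA6,205,0.16,0.04,64,18,397,53
DNA6,207,0.16,0.01,64,15,402,71
DNA6,209,0.32,0.01,103,8,325,29
DNA6,211,0.57,0.06,157,15,274,18
DNA7,201,13.5,1.4,272,5,20.4,2.2
DNA7,203,14.8,0.4,294,19,19.8,1.9
DNA7,205,13.4,1.8,239,10,18.0,2.4
DNA7,207,9.4,0.1,200,19,21.2,1.7
DNA7,209,8.5,1.7,144,22,17.6,5.5
DNA7,211,14.1,2.1,262,6,18.9,2.9
DNA8,201,15.0,1.6,288,31,19.1,0.1
DNA8,203,9.8,0.8,183,32,19.0,4.8
DNA8,205,9.8,0.8,108,13,11.2,2.1
DNA8,207,10.4,2.5,174,26,17.8,6.6
DNA8,209,14.8,1.6,233,17,15.8,1.9
DNA8,211,15.8,0.3,265,29,16.8,2.2
DNA9,201,4.2,0.4,7.0,0.8,1.7,0.2
DNA9,203,3.4,0.7,2.4,0.7,0.8,0.4
DNA9,205,0.3,0.1,0.9,0.2,3.3,0.3
DNA9,207,0.1,0.1,0.3,0.1,2.8,0.3
DNA9,209,1.7,0.1,4.3,0.4,2.5,0.2
DNA9,211,6.0,0.5,7.9,3.2,1.3,0.6
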