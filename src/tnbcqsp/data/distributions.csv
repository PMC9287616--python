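name,distribution_type,median,lower,upper,sd
D_T0,lognormal,3.0,1.0,10.0,0.4
k_C_growth,lognormal,0.025,0.005000000000000001,0.125,0.3
k_K_g,uniform,3.0,1.5,4.5,
EC50_nabp_C1,lognormal,3e-08,9.899999999999999e-10,9.899999999999998e-07,1.0
k_C_nabp,lognormal,0.105,0.014700000000000001,0.735,0.3
BSA,normal,1.8,1.4040000000000001,2.3040000000000003,0.2
r_nabp_tumor_plasma,lognormal,1.5,0.30000000000000004,7.5,0.3
PD1_dens_M,lognormal,30.0,0.99,900.0,0.5
PD1_dens_T,lognormal,25.0,1.0,750.0,0.5
PDL1_dens_C,lognormal,50.0,1.0,2500.0,0.8
CD47_dens_C,lognormal,250.0,10.0,6250.0,0.4
SIRPa_dens_M,lognormal,50.0,2.0,1250.0,0.4
CD80_dens_C,lognormal,10.0,0.4,250.0,0.4
k_Mac_mig,lognormal,150000.0,4500.0,4500000.0,0.5
k_M1_pol,lognormal,0.155,0.0062,3.7199999999999998,0.5
k_M2_pol,lognormal,0.5,0.05,5.0,0.3
k_MDSC_mig,lognormal,10500.0,420.0,315000.0,0.5
q_T_T_in,lognormal,0.024,0.00048,1.2,0.7
k_T_act,lognormal,2.75,0.275,27.5,0.5
k_Teff_C,lognormal,0.05,0.005000000000000001,0.5,0.5
k_Teff_Treg,lognormal,0.1,0.010000000000000002,1.0,0.5
k_C_Teff,lognormal,0.6,0.06,6.0,0.5
k_IL10_sec_M2,lognormal,0.000105,1.0500000000000001e-05,0.0010500000000000002,0.5
k_IFNg_sec_Teff,lognormal,4.1e-06,3.2799999999999997e-07,4.9199999999999997e-05,0.5
k_CCL2_sec_C,lognormal,0.00052,5.2e-05,0.0052,0.5
Q_nT_thym_Teff,lognormal,3647000.0,729400.0,18235000.0,0.3
Q_nT_thym_Th,lognormal,5838000.0,1167600.0,29190000.0,0.3
Q_nT_thym_Treg,lognormal,6058411.910670042,1211682.3821340085,30292059.55335021,0.3
k_T_death_Treg,lognormal,0.105,0.021,0.525,0.3
k_T_death_Th,lognormal,0.33,0.066,1.6500000000000001,0.3
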