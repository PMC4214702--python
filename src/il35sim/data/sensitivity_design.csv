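name,min,baseline,max,unit
lambda_c,0.225,0.45,0.9,1/day
d_n,0.2,0.4,0.8,1/day
eta,10,20,40,cm^3/g/day
s_q,1.25e-08,2.5e-08,5e-08,(g q)/(g c)/day
s_M,0.0001,0.0002,0.0004,g/cm^3/day
lambda_M_rho,0.015,0.03,0.06,g/cm^3/day
K_rho,2.5e-09,5e-09,1e-08,g/cm^3
chi_M,25000,50000,100000,cm^5/g/day
lambda_MQ,0.1,0.2,0.4,1/day
d_M,0.1,0.2,0.4,1/day
lambda_rho_c,5e-10,2.5e-08,3e-08,(g rho)/(g c)/day
lambda_rho_R,5e-08,1e-07,2e-07,(g rho)/(g R)/day
lambda_rho_M,1e-08,2e-08,4e-08,(g rho)/(g M)/day
d_rho,5,10,20,1/day
lambda_RM,0.0005,0.001,0.002,g/cm^3/day
lambda_R_beta,0.001,0.002,0.004,g/cm^3/day
d_R,0.1,0.2,0.4,1/day
lambda_beta_c,5e-09,1e-08,2e-08,(g beta)/(g c)/day
lambda_beta_R,1e-07,2e-07,4e-07,(g beta)/(g R)/day
lambda_T12,0.0075,0.015,0.03,g/cm^3/day
k_10M,0.5,1,2,dimensionless
k_MCP,0.5,1,2,dimensionless
k_12M,0.5,1,2,dimensionless
d_T,0.1,0.2,0.4,1/day
lambda_hc,1.09375e-07,2.1875e-07,4.375e-07,(g h)/(g c)/day
lambda_hM,1e-07,2e-07,4e-07,(g h)/(g M)/day
chi_e,250000,500000,1000000,cm^5/g/day
lambda_e,0.25,0.5,1,1/day
lambda_w,10000,20000,40000,cm^3/g/day
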