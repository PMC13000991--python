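id,role,arm,baseline,low,high,distribution,note
p_nocav_cavity,probability,standard,0.06873,0.0665,0.071,beta,Progression no-cavity to cavity per 6-month cycle (SB Brasil 2010)
q_gic,probability,both,0.873,0.869,0.877,beta,Cavity treated with glass ionomer cement (SB Brasil 2010)
q_hall,probability,both,0.004,0.003,0.005,beta,Cavity treated with Hall technique (SB Brasil 2010)
s_gic,probability,both,0.63,0.49,0.74,beta,Glass ionomer success then previous-cavity (Araujo 2020)
s_hall,probability,both,0.98,0.88,0.99,beta,Hall technique success then previous-cavity (Araujo 2020)
p_prev_cavity,probability,standard,0.28,0.14,0.58,beta,Relapse previous-cavity to cavity (Guedes 2017)
eff_rr,relative-risk,fv,0.88,0.81,0.95,lognormal,Fluoride varnish pooled relative risk (de Sousa 2019 meta-analysis)
fv_p_nocav_cavity,probability,fv,0.0604824,0.0586,0.0625,beta,FV arm progression 0.06873 x 0.88 with printed DSA bounds
fv_f_gic,probability,fv,0.3256,0.2288,0.4488,beta,FV arm glass ionomer failure 0.37 x 0.88
fv_f_hall,probability,fv,0.0176,0.0088,0.1056,beta,FV arm Hall failure 0.02 x 0.88
fv_p_prev_cavity,probability,fv,0.2464,0.1232,0.5104,beta,FV arm relapse 0.28 x 0.88
c_routine,cost,both,118.50,94.8,142.2,gamma,Routine visit cost per cycle in every state (2022 BRL FioSaude)
c_gic,cost,both,179.50,143.6,215.4,gamma,Glass ionomer restoration (2022 BRL)
c_hall,cost,both,254.50,203.6,305.4,gamma,Hall technique restoration (2022 BRL)
c_ext,cost,both,172.50,138.0,207.0,gamma,Tooth extraction (2022 BRL)
c_fv,cost,fv,78.00,62.4,93.6,gamma,FV application on both arches per cycle (2022 BRL)
daly_weight,disability-weight,both,0.01,0.01,0.01,fixed,DALY weight per year lived with a cavitated primary-tooth lesion (GBD 2019)
discount_rate_annual,rate,both,0.05,0.05,0.05,fixed,Annual discount rate applied to costs and effects
n_cycles,count,both,8,8,8,fixed,Number of 6-month cycles (4-year horizon)
cycle_length_years,rate,both,0.5,0.5,0.5,fixed,Cycle length in years
wtp_daly,cost,both,40000,40000,40000,fixed,Willingness to pay per DALY avoided (approx. 1 GDP per capita)
wtp_cavity,cost,both,60,60,60,fixed,Willingness to pay per cavity avoided (private-payer study)
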