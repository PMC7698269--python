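preset,temp_target_c,temp_realized_c,yield_kg_m2,income_eur_m2,net_profit_eur_m2,trusses_per_stem,fruits_per_m2,max_plant_load,mean_brix,heat_mj_m2,electricity_kwh_m2,co2_dosed_kg_m2,water_uptake_l_m2
301,21.34,21.35,13.62,34.77,4.12,23.4,1574,776,8.81,491.1,194.3,11.1,345.0
302,22.04,21.98,13.6,34.53,4.94,21.6,1357,788,8.85,523.3,192.1,10.3,338.3
303,22.7,22.67,13.36,34.39,1.82,22.8,1326,650,8.66,558.6,196.0,8.2,345.2
304,21.37,21.3,13.57,34.53,5.23,22.1,1404,772,8.78,488.1,192.1,10.3,338.3
305,21.4,21.36,14.01,35.9,6.53,22.0,1427,768,9.05,489.7,200.7,7.9,347.4
306,23.25,23.27,13.45,34.67,4.08,24.2,1359,706,8.87,595.3,193.8,9.5,341.5
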