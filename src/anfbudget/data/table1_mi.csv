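# Published nitrogen mass balance, MI switchgrass fertilization trial, 2009-2015.
# Units: deposition/N output/balance kg N ha-1 yr-1; yield Mg dry mass ha-1.
# printed_balance/printed_balance_se are the published cells, kept for cross-checks;
# the ledger recomputes balances from deposition + fertilizer - n_output.
site,year,treatment_kg_n,deposition_kg_n,optimal_n,yield_mg_ha,yield_se,n_output_kg,n_output_se,printed_balance,printed_balance_se
MI,2009,0,5.2,147,2.0,0.2,6.2,0.5,-1.0,0.5
MI,2010,0,5.7,72,6.2,0.4,19.0,2.6,-13.3,2.6
MI,2011,0,8.0,34,9.6,0.2,41.4,3.8,-33.4,3.8
MI,2012,0,5.6,0,7.2,0.6,31.1,2.8,-25.5,2.8
MI,2013,0,7.3,0,11.9,0.4,70.4,9.5,-63.1,9.5
MI,2014,0,6.1,0,11.3,0.7,65.2,4.3,-59.1,4.3
MI,2015,0,5.6,109,10.9,0.9,56.7,10.1,-51.1,10.0
MI,2009,56,5.2,147,3.6,0.2,16.0,0.7,45.3,0.7
MI,2010,56,5.7,72,9.3,1.2,39.0,1.8,22.7,1.8
MI,2011,56,8.0,34,10.6,0.4,68.7,5.6,-4.6,5.6
MI,2012,56,5.6,0,7.4,0.2,47.8,1.2,13.8,1.2
MI,2013,56,7.3,0,11.6,0.7,87.9,7.8,-24.6,7.8
MI,2014,56,6.1,0,11.8,0.5,84.4,3.9,-22.3,3.9
MI,2015,56,5.6,109,12.3,0.1,93.7,3.5,-32.0,3.5
MI,2009,196,5.2,147,4.3,0.4,28.8,2.5,172.6,2.5
MI,2010,196,5.7,72,8.3,0.7,62.5,5.7,139.3,5.7
MI,2011,196,8.0,34,10.8,1.1,83.7,7.3,120.5,7.3
MI,2012,196,5.6,0,5.5,0.2,45.9,2.0,155.8,2.0
MI,2013,196,7.3,0,10.7,0.5,101.6,5.7,101.8,5.7
MI,2014,196,6.1,0,12.0,0.4,109.9,3.6,92.3,3.6
MI,2015,196,5.6,109,12.9,0.4,92.9,4.0,108.9,4.0
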