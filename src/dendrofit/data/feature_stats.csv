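target,stimulus,feature,mean,sd,unit
step,low,spike_frequency,9,0.88,Hz
step,low,adaptation_index,0.0036,0.0091,1
step,low,isi_cv,0.1204,0.0321,1
step,low,initial_burst_isi,57.75,33.48,ms
step,low,first_spike_latency,43.25,7.32,ms
step,low,ap_peak,26.23,4.97,mV
step,low,fast_ahp_depth,-51.95,5.82,mV
step,low,slow_ahp_depth,-58.04,4.58,mV
step,low,slow_ahp_time,0.238,0.030,fraction_of_isi
step,low,ap_half_width,1.31,0.17,ms
step,ref,spike_frequency,14.5,0.56,Hz
step,ref,adaptation_index,0.0023,0.0056,1
step,ref,isi_cv,0.1083,0.0368,1
step,ref,initial_burst_isi,6.625,8.65,ms
step,ref,first_spike_latency,19.13,7.31,ms
step,ref,ap_peak,16.52,6.11,mV
step,ref,fast_ahp_depth,-54.19,5.57,mV
step,ref,slow_ahp_depth,-60.51,4.67,mV
step,ref,slow_ahp_time,0.279,0.027,fraction_of_isi
step,ref,ap_half_width,1.38,0.28,ms
step,high,spike_frequency,22.5,2.22,Hz
step,high,adaptation_index,0.0046,0.0026,1
step,high,isi_cv,0.0954,0.0140,1
step,high,initial_burst_isi,5.38,0.83,ms
step,high,first_spike_latency,7.25,1,ms
step,high,ap_peak,16.44,6.93,mV
step,high,fast_ahp_depth,-56.56,3.58,mV
step,high,slow_ahp_depth,-59.99,3.92,mV
step,high,slow_ahp_time,0.213,0.037,fraction_of_isi
step,high,ap_half_width,1.86,0.41,ms
bac,bac,ca_spike_peak,6.73,2.54,mV
bac,bac,ca_spike_width,37.43,1.27,ms
bac,bac,ap_count_coincident,3,0,count
bac,bac,mean_ap_isi,9.9,0.85,ms
bac,bac,ahp_depth,-65,4,mV
bac,bac,ap_peak,25,5,mV
bac,bac,ap_half_width,2,0.5,ms
bac,bac,ap_count_soma_only,1,0,count
bac,bac,bap_amp_620,45,10,mV
bac,bac,bap_amp_800,36,9.33,mV
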