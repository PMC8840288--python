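feature,no_stress_mean,no_stress_sd,stress_mean,stress_sd,p_value,direction,unit
mu_NN,788,126,642,96,0.005,decreases_with_stress,ms
mu_HR,78.45,12.38,95.54,13.69,0.005,increases_with_stress,bpm
sigma_HR,6.43,1.15,10.48,3.88,0.001,increases_with_stress,bpm
RMSSD_NN,0.04,0.02,0.03,0.01,0.018,decreases_with_stress,s
pNN50,22.89,19.44,7.35,4.98,0.043,decreases_with_stress,%
mu_EMG,,,,,,increases_with_stress,mV
RMS_EMG,,,,,,increases_with_stress,mV
RMS50P_EMG,,,,,,increases_with_stress,mV
mu_RespRate,,,,,,increases_with_stress,breaths/min
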