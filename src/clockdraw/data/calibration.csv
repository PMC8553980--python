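cohort,condition,total_time_med,total_time_q1,total_time_q3,ink_length_med,ink_length_q1,ink_length_q3,drawing_size_med,drawing_size_q1,drawing_size_q3,percent_think_med,percent_think_q1,percent_think_q3,average_latency_med,longest_latency_med,longest_latency_q1,longest_latency_q3,intra_latency_med,intra_latency_sigma,inter_latency_sigma,latency_calib,average_speed_med,average_speed_q1,average_speed_q3,max_speed_med,initiation_speed_med,termination_speed_med,circularity_med,circularity_q1,circularity_q3,tremor_amp_mm,tremor_hz,digit_jitter_rad,hand_jitter_rad,digit_radius_frac,radial_jitter_frac,hour_hand_frac,minute_hand_frac,hand_len_jitter,vertical_offset_med,center_x_sd,noise_rate,noise_len_med,noise_len_sigma,omission_rate,overwrite_rate,crossout_rate
unimpaired,command,34.37,27.48,42.98,580.32,470.2,694.1,80.29,65.69,94.16,59.48,54.01,65.19,0.84,4.46,2.94,6.84,0.20,0.40,0.55,1.0,127.09,91.95,170.8,208.9,109.59,117.93,2.38,2.21,2.60,0.90,6.0,0.10,0.70,0.78,0.04,0.45,0.62,0.08,6.75,8.0,0.8,5.0,0.5,0.12,0.18,0.02
impaired,command,44.42,32.04,65.01,480.08,365.47,637.09,64.06,46.66,82.06,62.10,54.78,69.95,1.18,6.87,4.16,11.64,0.20,0.40,0.60,1.0,81.47,54.75,129.92,158.17,76.18,72.43,2.59,2.36,2.83,0.41,6.5,0.22,1.25,0.78,0.07,0.45,0.62,0.12,10.25,12.0,1.6,8.0,0.5,0.45,0.45,0.08
unimpaired,copy,26.22,22.28,32.49,440.93,390.92,495.32,59.15,52.92,67.71,53.70,49.00,58.12,0.62,1.98,1.50,2.83,0.20,0.40,0.45,1.0,100.37,73.59,138.40,168.30,85.16,94.97,2.36,2.19,2.61,0.62,6.0,0.11,0.75,0.78,0.04,0.45,0.62,0.08,10.34,8.0,0.8,4.0,0.5,0.06,0.10,0.02
impaired,copy,32.12,25.41,43.58,392.1,341.4,464.6,50.95,44.18,59.52,55.84,49.20,62.46,0.80,3.12,2.09,5.37,0.20,0.40,0.55,1.0,78.74,51.16,113.3,140.3,68.08,71.90,2.55,2.33,2.80,0.39,6.5,0.21,1.20,0.78,0.06,0.45,0.62,0.12,19.77,12.0,1.6,7.0,0.5,0.25,0.30,0.05
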