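metric,sex,decade,lower_lo,lower_hi,mean,upper_lo,upper_hi
global_fd,male,20-29,1.141,1.156,1.199,1.243,1.257
global_fd,male,30-39,1.148,1.163,1.206,1.250,1.264
global_fd,male,40-49,1.155,1.169,1.213,1.256,1.271
global_fd,male,50-59,1.161,1.176,1.220,1.263,1.284
global_fd,male,60-69,1.168,1.183,1.226,1.270,1.284
mean_apical_fd,male,20-29,1.147,1.167,1.226,1.286,1.306
mean_apical_fd,male,30-39,1.150,1.170,1.230,1.290,1.310
mean_apical_fd,male,40-49,1.153,1.173,1.233,1.293,1.313
mean_apical_fd,male,50-59,1.157,1.177,1.236,1.296,1.316
mean_apical_fd,male,60-69,1.160,1.180,1.240,1.300,1.320
max_apical_fd,male,20-29,1.209,1.229,1.286,1.344,1.363
max_apical_fd,male,30-39,1.212,1.231,1.289,1.347,1.366
max_apical_fd,male,40-49,1.215,1.234,1.292,1.350,1.369
max_apical_fd,male,50-59,1.218,1.237,1.295,1.353,1.372
max_apical_fd,male,60-69,1.221,1.240,1.298,1.356,1.375
strain_circumferential,male,20-29,-15.1,-16.2,-19.4,-22.5,-23.6
strain_circumferential,male,30-39,-15.2,-16.3,-19.4,-22.6,-23.7
strain_circumferential,male,40-49,-15.3,-16.4,-19.5,-22.7,-23.8
strain_circumferential,male,50-59,-15.4,-16.5,-19.6,-22.8,-23.9
strain_circumferential,male,60-69,-15.5,-16.6,-19.7,-22.9,-24.0
strain_radial,male,20-29,24.5,28.6,40.8,53.0,57.1
strain_radial,male,30-39,25.3,29.4,41.6,53.8,57.9
strain_radial,male,40-49,26.1,30.2,42.4,54.6,58.7
strain_radial,male,50-59,26.9,31.0,43.2,55.4,59.5
strain_radial,male,60-69,27.7,31.8,44.0,56.2,60.3
strain_longitudinal,male,20-29,-14.2,-15.2,-18.4,-21.5,-22.6
strain_longitudinal,male,30-39,-14.3,-15.3,-18.4,-21.6,-22.6
strain_longitudinal,male,40-49,-14.3,-15.4,-18.5,-21.6,-22.7
strain_longitudinal,male,50-59,-14.4,-15.4,-18.6,-21.7,-22.7
strain_longitudinal,male,60-69,-14.5,-15.5,-18.6,-21.8,-22.8
global_fd,female,20-29,1.133,1.146,1.190,1.232,1.247
global_fd,female,30-39,1.134,1.149,1.191,1.234,1.249
global_fd,female,40-49,1.136,1.150,1.193,1.236,1.250
global_fd,female,50-59,1.138,1.152,1.195,1.238,1.252
global_fd,female,60-69,1.140,1.154,1.197,1.240,1.254
mean_apical_fd,female,20-29,1.109,1.131,1.197,1.264,1.286
mean_apical_fd,female,30-39,1.109,1.131,1.197,1.263,1.286
mean_apical_fd,female,40-49,1.108,1.131,1.197,1.263,1.285
mean_apical_fd,female,50-59,1.108,1.130,1.197,1.263,1.285
mean_apical_fd,female,60-69,1.108,1.130,1.196,1.263,1.285
max_apical_fd,female,20-29,1.174,1.197,1.265,1.333,1.355
max_apical_fd,female,30-39,1.173,1.196,1.263,1.331,1.354
max_apical_fd,female,40-49,1.172,1.194,1.262,1.330,1.353
max_apical_fd,female,50-59,1.170,1.193,1.261,1.329,1.351
max_apical_fd,female,60-69,1.169,1.191,1.259,1.327,1.350
strain_circumferential,female,20-29,-15.0,-16.3,-20.2,-24.1,-25.4
strain_circumferential,female,30-39,-16.0,-17.3,-21.2,-25.1,-26.4
strain_circumferential,female,40-49,-17.1,-18.4,-22.2,-26.1,-27.4
strain_circumferential,female,50-59,-18.1,-19.4,-23.3,-27.1,-28.4
strain_circumferential,female,60-69,-19.1,-20.4,-24.3,-28.2,-29.5
strain_radial,female,20-29,23.8,29.1,44.8,60.6,65.8
strain_radial,female,30-39,27.4,32.7,48.5,64.2,69.5
strain_radial,female,40-49,31.1,36.3,52.1,67.8,73.1
strain_radial,female,50-59,34.7,39.9,55.7,71.5,76.7
strain_radial,female,60-69,38.3,43.6,59.3,75.1,80.3
strain_longitudinal,female,20-29,-16.9,-17.9,-21.1,-24.2,-25.3
strain_longitudinal,female,30-39,-17.0,-18.0,-21.2,-24.3,-25.4
strain_longitudinal,female,40-49,-17.1,-18.2,-21.3,-24.5,-25.5
strain_longitudinal,female,50-59,-17.3,-18.3,-21.5,-24.6,-25.7
strain_longitudinal,female,60-69,-17.4,-18.4,-21.6,-24.7,-25.8
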