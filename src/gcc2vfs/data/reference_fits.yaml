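# Published per-area fits from the original 83-eye primary open-angle
# glaucoma cohort (right eyes; HFA 10-2 mean sensitivities vs RS-3000
# macular GCC thickness).  Used as reference values in tests and as
# default generative truth for the synthetic cohort.
n_eyes: 83

# Multiple logistic model: VFS = theta1 / (1 + exp(b0 + b1*gcc + b2*age + b3*sex + b4*se))
multiple:
  whole:    {theta1: 32.354,  b0: 5.308,    b1: -0.103,   b2: 0.011,    b3: 0.562,    b4: 0.075}
  superior: {theta1: 33.550,  b0: 4.011,    b1: -0.088,   b2: 0.019,    b3: 0.163,    b4: 0.075}
  inferior: {theta1: 31.373,  b0: 8.005,    b1: -0.150,   b2: 0.012,    b3: 0.631,    b4: 0.065}
  "3_1":      {theta1: 34.354,  b0: 2.099,    b1: -0.078,   b2: 0.017,    b3: 0.809,    b4: -0.047}
  "3_2":      {theta1: 33.771,  b0: 5.886,    b1: -0.083,   b2: -0.019,   b3: 0.860,    b4: 0.287}
  "3_3":      {theta1: 33.617,  b0: 6.322,    b1: -0.115,   b2: 0.000,    b3: 0.982,    b4: -0.023}
  "3_4":      {theta1: 32.497,  b0: 15.490,   b1: -0.254,   b2: -0.018,   b3: -0.023,   b4: -0.107}
  "6_1":      {theta1: 32.2688, b0: 7.330959, b1: -0.15208, b2: 0.01438,  b3: 0.193122, b4: 0.16887}
  "6_2":      {theta1: 31.84307, b0: 8.16703, b1: -0.15263, b2: 0.030713, b3: 0.448431, b4: 0.24115}
  "6_3":      {theta1: 31.78739, b0: 12.31516, b1: -0.21936, b2: -0.0143, b3: 0.840679, b4: 0.07381}
  "6_4":      {theta1: 30.48275, b0: 7.47111, b1: -0.17642, b2: 0.046105, b3: 0.972715, b4: 0.08507}

# Simple logistic model: VFS = theta1 / (1 + exp(-theta3 * (gcc - theta2)))
simple:
  whole:    {theta1: 33.479, theta2: 56.629, theta3: 0.080}
  superior: {theta1: 34.303, theta2: 54.999, theta3: 0.076}
  inferior: {theta1: 31.781, theta2: 58.076, theta3: 0.139}
  "3_1":      {theta1: 34.239, theta2: 46.506, theta3: 0.082}
  "3_2":      {theta1: 35.114, theta2: 51.061, theta3: 0.057}
  "3_3":      {theta1: 33.386, theta2: 59.917, theta3: 0.135}
  "3_4":      {theta1: 32.656, theta2: 59.154, theta3: 0.197}
  "6_1":      {theta1: 33.758, theta2: 49.706, theta3: 0.099}
  "6_2":      {theta1: 32.765, theta2: 58.038, theta3: 0.088}
  "6_3":      {theta1: 32.129, theta2: 52.983, theta3: 0.212}
  "6_4":      {theta1: 31.490, theta2: 56.007, theta3: 0.102}

# Goodness-of-fit p, model-effect ANOVA F, and R² as published.
diagnostics_multiple:
  whole:    {gof_p: 0.9966, F: 206.1, r2: 0.72}
  superior: {gof_p: 0.9979, F: 189.8, r2: 0.70}
  inferior: {gof_p: 0.3876, F: 267.3, r2: 0.77}
  "3_1":      {gof_p: 0.9996, F: 179.1, r2: 0.69}
  "3_2":      {gof_p: 1.0000, F: 180.5, r2: 0.69}
  "3_3":      {gof_p: 0.1497, F: 408.4, r2: 0.83}
  "3_4":      {gof_p: 0.9995, F: 252.6, r2: 0.76}
  "6_1":      {gof_p: 0.2182, F: 160.4, r2: 0.66}
  "6_2":      {gof_p: 0.9928, F: 290.7, r2: 0.78}
  "6_3":      {gof_p: 0.0001, F: 179.4, r2: 0.69}
  "6_4":      {gof_p: 0.7366, F: 236.2, r2: 0.74}

diagnostics_simple:
  whole:    {gof_p: 0.9606, F: 144.8, r2: 0.64}
  superior: {gof_p: 0.9344, F: 128.3, r2: 0.61}
  inferior: {gof_p: 0.0698, F: 210.1, r2: 0.72}
  "3_1":      {gof_p: 0.9990, F: 115.7, r2: 0.59}
  "3_2":      {gof_p: 0.9501, F: 91.0,  r2: 0.53}
  "3_3":      {gof_p: 0.0413, F: 295.7, r2: 0.78}
  "3_4":      {gof_p: 0.9982, F: 234.4, r2: 0.74}
  "6_1":      {gof_p: 0.0317, F: 110.1, r2: 0.58}
  "6_2":      {gof_p: 0.0593, F: 104.2, r2: 0.56}
  "6_3":      {gof_p: 0.0001, F: 156.3, r2: 0.66}
  "6_4":      {gof_p: 0.0084, F: 106.2, r2: 0.57}
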