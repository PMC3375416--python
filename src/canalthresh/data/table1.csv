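condition,shape,frequency_hz,period_s,threshold_deg_s,sem_plus,sem_minus,source
I,triangular,0.15,6.7,1.984,0.373,0.314,measured
II,sinusoidal,0.15,6.7,2.552,0.552,0.454,measured
III,trapezoidal,0.15,6.7,2.124,0.457,0.376,measured
IV,triangular,0.7,1.4,0.939,0.111,0.099,measured
V,sinusoidal,0.7,1.4,1.051,0.112,0.101,measured
VI,trapezoidal,0.7,1.4,0.897,0.107,0.096,measured
VII,triangular,3,0.3,0.804,0.030,0.029,measured
VIII,sinusoidal,3,0.3,0.778,0.051,0.049,measured
IX,trapezoidal,3,0.3,0.766,0.038,0.036,measured
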