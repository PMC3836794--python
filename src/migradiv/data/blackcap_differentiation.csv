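code,Sv,Ub,Fr_NW,Fr_SW,Wh,Mn,Os,Kf,Vn,Ry,Bw,Km
Sv,0,0.057,0.059,0.035,0.017,0.029,0.020,0.022,0.014,0.051,0.038,0.008
Ub,0.054,0,0.028,0.004,0.004,0.000,0.000,0.005,0.000,0.001,0.000,0.041
Fr_NW,0.056,0.027,0,0.030,0.030,0.008,0.020,0.007,0.009,0.025,0.020,0.071
Fr_SW,0.034,0.004,0.029,0,0.018,0.000,0.000,0.000,0.004,0.010,0.001,0.021
Wh,0.017,0.004,0.029,0.017,0,0.009,0.000,0.004,0.000,0.013,0.000,0.032
Mn,0.029,0.000,0.008,0.000,0.009,0,0.000,0.004,0.000,0.005,0.005,0.025
Os,0.020,0.000,0.019,0.000,0.000,0.000,0,0.006,0.000,0.007,0.000,0.002
Kf,0.022,0.005,0.007,0.000,0.004,0.004,0.006,0,0.000,0.010,0.001,0.040
Vn,0.014,0.000,0.009,0.004,0.000,0.000,0.000,0.000,0,0.003,0.000,0.034
Ry,0.048,0.001,0.024,0.010,0.013,0.005,0.007,0.009,0.003,0,0.000,0.049
Bw,0.036,0.000,0.019,0.001,0.000,0.005,0.000,0.001,0.000,0.000,0,0.016
Km,0.008,0.040,0.066,0.020,0.031,0.025,0.002,0.038,0.033,0.046,0.016,0
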