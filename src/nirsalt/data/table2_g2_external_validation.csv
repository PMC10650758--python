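sample_id,na_real,k_real,na_plus_k,predicted,cf,na_calc
N1,1.21,1.66,2.87,1.76,0.69,1.11
N2,1.06,1.80,2.86,1.75,0.61,1.10
N3,1.09,1.64,2.73,1.63,0.67,1.03
N4,1.12,1.76,2.88,1.80,0.62,1.13
N5,1.07,1.37,2.44,1.53,0.70,0.96
N6,0.82,1.57,2.39,1.49,0.55,0.94
N7,0.85,1.43,2.28,1.37,0.62,0.86
N8,0.80,1.53,2.33,1.36,0.59,0.86
N9,0.81,1.67,2.48,1.44,0.56,0.91
N10,1.25,1.77,3.02,1.79,0.70,1.13
N11,1.16,1.78,2.94,1.70,0.68,1.07
N12,1.08,1.70,2.78,1.74,0.62,1.10
N13,1.01,1.56,2.57,1.78,0.57,1.12
N14,0.87,1.52,2.39,1.35,0.64,0.85
N15,0.86,1.22,2.08,1.41,0.61,0.89
N16,0.80,1.46,2.26,1.37,0.58,0.86
N17,0.85,1.55,2.40,1.43,0.59,0.90
N18,1.07,1.73,2.80,1.63,0.66,1.03
N19,0.87,1.33,2.20,1.36,0.64,0.86
N20,0.91,1.28,2.19,1.34,0.68,0.84
N21,0.88,1.23,2.11,1.28,0.69,0.81
N22,0.83,1.23,2.06,1.31,0.63,0.83
N23,1.04,1.61,2.65,1.63,0.64,1.03
N24,1.14,1.68,2.82,1.73,0.66,1.09
N25,0.99,1.51,2.50,1.58,0.63,1.00
N26,0.81,1.27,2.08,1.33,0.61,0.84
N27,0.89,1.28,2.17,1.43,0.62,0.90
N28,1.07,1.76,2.83,1.81,0.59,1.14
N29,1.00,1.70,2.70,1.72,0.58,1.08
N30,1.01,1.46,2.47,1.55,0.65,0.98
N31,1.03,1.58,2.61,1.60,0.64,1.01
N32,0.84,1.39,2.23,1.42,0.59,0.89
N33,0.95,1.59,2.54,1.70,0.56,1.07
N34,0.91,1.40,2.31,1.44,0.63,0.91
N35,0.80,1.21,2.01,1.32,0.61,0.83
N36,0.88,1.24,2.12,1.29,0.68,0.81
N37,0.83,1.15,1.98,1.23,0.67,0.77
N38,0.77,1.18,1.95,1.25,0.62,0.79
N39,0.81,1.12,1.93,1.18,0.69,0.74
N40,0.97,1.58,2.55,1.64,0.59,1.03
N41,1.04,1.51,2.55,1.57,0.66,0.99
N42,1.00,1.49,2.49,1.54,0.65,0.97
N43,0.92,1.40,2.32,1.45,0.63,0.91
N44,0.87,1.37,2.24,1.43,0.61,0.90
N45,0.92,1.53,2.45,1.56,0.59,0.98
N46,0.87,1.12,1.99,1.21,0.72,0.76
N47,0.92,1.15,2.07,1.17,0.79,0.85
N48,0.87,1.13,2.00,1.19,0.73,0.75
N49,0.92,1.04,1.96,1.15,0.80,0.84
N50,0.80,1.08,1.88,1.19,0.67,0.75
N51,0.91,1.25,2.16,1.32,0.69,0.83
N52,0.86,1.20,2.06,1.27,0.68,0.80
N53,0.98,1.48,2.46,1.51,0.65,0.95
N54,0.90,1.56,2.46,1.63,0.55,1.03
N55,0.90,1.34,2.24,1.43,0.63,0.90
N56,0.90,1.42,2.32,1.45,0.62,0.91
N57,0.89,1.55,2.44,1.58,0.56,1.00
N58,1.10,1.66,2.76,1.75,0.63,1.10
N59,1.06,1.75,2.81,1.83,0.58,1.15
N60,0.80,1.26,2.06,1.30,0.62,0.82
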