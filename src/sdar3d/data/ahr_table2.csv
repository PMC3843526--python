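compound_id,experimental,pls_2ppm,knn_2ppm,pls_10ppm,knn_10ppm,consensus,flag
"3,3',4,4'-Tetrachlorobiphenyl",6.15,6.02,5.50,6.49,5.75,6.00,
"2,3,4,4'-Tetrachlorobiphenyl",4.55,5.27,5.35,5.15,5.28,5.25,
"3,3',4,4',5-Pentachlorobiphenyl",6.89,5.06,5.11,5.96,5.63,5.54,
"2',3,4,4',5-Pentachlorobiphenyl",4.85,4.77,5.26,4.23,5.11,4.75,
"2,3,3',4,4'-Pentachlorobiphenyl",5.37,5.59,5.64,5.07,5.38,5.36,
"2,3',4,4',5-Pentachlorobiphenyl",5.04,5.47,5.47,4.74,5.29,5.11,
"2,3,4,4',5-Pentachlorobiphenyl",5.39,4.81,4.78,5.53,5.14,5.16,
"2,3,3',4,4',5-Hexachlorobiphenyl",5.15,5.33,5.22,5.61,5.19,5.42,
"2,3',4,4',5,5'-Hexachlorobiphenyl",4.80,5.16,5.41,4.80,5.36,5.11,
"2,3,3'4,4',5'-Hexachlorobiphenyl",5.33,5.23,5.12,5.07,5.37,5.10,
"2,2',4,4'-Tetrachlorobiphenyl",3.89,5.22,4.83,4.49,4.94,4.66,
"2,2',4,4'5,5'-Hexachlorobiphenyl",4.10,4.41,5.05,3.50,4.85,4.28,
"2,3,4,5-Tetrachlorobiphenyl",3.85,5.55,5.20,5.35,5.29,5.28,
"2,3',4,4',5',6-Hexachlorobiphenyl",4.00,5.44,5.23,4.37,4.90,4.80,
"4'-Hydroxy-2,3,4,5-tetrachlorobiphenyl",4.05,5.88,5.05,5.07,4.86,5.07,consensus_print_mismatch
"4'-Methyl-2,3,4,5-tetrachlorobiphenyl",4.51,5.21,5.27,5.13,4.86,5.20,
"4'-Fluoro-2,3,4,5-tetrachlorobiphenyl",4.60,5.13,4.92,4.37,4.67,4.65,
"4'-Methoxy-2,3,4,5-tetrachlorobiphenyl",4.80,5.35,5.15,4.32,4.74,4.74,
"4'-Acetyl-2,3,4,5-tetrachlorobiphenyl",5.17,5.00,4.87,4.14,4.98,4.51,
"4'-Cyano-2,3,4,5-tetrachlorobiphenyl",5.27,5.48,5.05,4.29,4.78,4.67,
"4'-Ethyl-2,3,4,5-tetrachlorobiphenyl",5.46,5.13,5.06,4.50,4.82,4.78,
"4'-Bromo-2,3,4,5-tetrachlorobiphenyl",5.60,5.42,5.34,5.27,5.51,5.31,
"4'-Iodo-2,3,4,5-tetrachlorobiphenyl",5.82,5.53,5.16,5.88,5.84,5.52,
"4'-isopropyl-2,3,4,5-tetrachlorobiphenyl",5.89,5.77,5.45,5.07,4.75,5.26,
"4'-Trifluromethyl-2,3,4,5-tetrachlorobiphenyl",6.43,5.42,5.25,4.46,4.80,4.86,
"3'-Nitro-2,3,4,5-tetrachlorobiphenyl",4.85,5.51,5.27,5.07,4.75,5.17,
"4'-N-Acetylamino-2,3,4,5-tetrachlorobiphenyl",5.09,5.26,4.87,5.09,4.96,4.98,
"4'-Phenyl-2,3,4,5-tetrachlorobiphenyl",5.18,4.74,5.03,4.69,5.01,4.86,
"4'-t-Butyl-2,3,4,5-tetrachlorobiphenyl",5.17,5.12,5.34,4.71,4.89,5.03,
"4'-n-Butyl-2,3,4,5-tetrachlorobiphenyl",5.13,5.12,5.13,5.44,4.93,5.29,
"2,3,7,8-Tetrachlorodibenzo-p-dioxin",8.00,8.27,7.66,7.10,7.28,7.38,
"1,2,3,7,8-Pentachlorodibenzo-p-dioxin",7.10,6.10,6.73,6.43,5.99,6.58,
"2,3,6,7-Tetrachlorodibenzo-p-dioxin",6.80,6.56,6.76,5.92,5.96,6.34,
"2,3,6-Trichlorodibenzo-p-dioxin",6.66,6.31,6.67,5.85,5.90,6.26,
"1,2,3,4,7,8-Hexachlorodibenzo-p-dioxin",6.55,5.83,6.10,5.84,5.69,5.97,
"1,3,7,8-Tetrachlorodibenzo-p-dioxin",6.10,6.22,6.68,6.03,6.12,6.36,
"1,2,4,7,8-Pentachlorodibenzo-p-dioxin",5.96,5.99,6.46,5.41,5.86,5.94,
"1,2,3,4-Tetrachlorodibenzo-p-dioxin",5.89,4.39,5.44,5.96,5.87,5.70,
"2,3,7-Trichlorodibenzo-p-dioxin",7.15,6.72,6.84,6.69,7.37,6.77,
"2,8-Dichlorodibenzo-p-dioxin",5.50,5.73,6.04,7.83,7.94,6.94,
"1,2,3,4,7-Pentachlorodibenzo-p-dioxin",5.19,5.68,6.02,5.69,5.95,5.86,
"1,2,4-Trichlorodibenzo-p-dioxin",4.89,5.46,5.90,6.12,5.99,6.01,
"1,2,3,4,6,7,8,9-octachlorodibenzo-p-dioxin",5.00,6.78,7.76,4.77,5.74,6.27,
1-Chlorodibenzo-p-dioxin,4.00,5.97,6.09,6.44,6.54,6.28,consensus_print_mismatch
"2,3,7,8-Tetra bromodibenzo-p-dioxin",8.82,9.29,8.61,9.86,8.43,9.24,
"2,3-Dibromo-7,8-dichlorodibenzo-p-dioxin",8.83,8.56,8.43,8.55,8.15,8.49,
"2,8-Dibromo-3,7-dichlorodibenzo-p-dioxin",9.35,7.54,7.86,6.87,7.06,7.37,
"2-Bromo-3,7,8-trichlorodibenzo-p-dioxin",7.94,8.31,8.05,7.26,7.40,7.66,
"1,3,7,8,9-Pentabromodibenzo-p-dioxin",7.03,7.25,7.99,7.53,8.29,7.76,
"1,3,7,8,-Tetrabromodibenzo-p-dioxin",8.70,7.38,8.51,8.22,8.48,8.37,
"1,2,4,7,8-Pentabromodibenzo-p-dioxin",7.77,7.31,8.06,9.20,8.24,8.63,
"1,2,3,7,8-Pentabromodibenzo-p-dioxin",8.18,8.31,8.65,8.40,8.57,8.53,
"2,3,7-Tribromodibenzo-p-dioxin",8.93,8.10,8.40,8.23,8.42,8.32,
"2,7-Dibromodibenzo-p-dioxin",7.81,7.48,7.36,7.07,8.06,7.22,
2-Bromodibenzo-p-dioxin,6.53,6.67,7.03,8.22,7.73,7.63,
2-Chlorodibenzofuran,3.55,3.94,4.48,3.76,3.78,4.12,
3-Chlorodibenzofuran,4.38,5.13,5.01,5.75,5.89,5.38,
4-Chlorodibenzofuran,3.00,5.20,4.54,4.80,5.37,4.67,
"2,3-Dichlorodibenzofuran",5.33,5.29,4.77,5.68,5.71,5.23,
"2,6-Dichlorodibenzofuran",3.61,5.03,4.85,3.50,4.14,4.18,
"2,8-Dichlorodibenzofuran",3.59,4.21,4.77,3.76,3.88,4.27,
"1,3,6-Trichlorodibenzofuran",5.36,6.28,6.21,5.70,5.57,5.96,
"1,3,8-Trichlorodibenzofuran",4.07,5.80,5.82,5.28,5.40,5.55,
"2,3,4-Trichlorodibenzofuran",4.72,6.78,5.80,5.73,5.83,5.77,
"2,3,8-Trichlorodibenzofuran",6.00,5.58,5.07,5.63,5.59,5.35,
"2,6,7 -Trichlorodibenzofuran",6.35,5.64,5.29,5.38,4.98,5.34,
"2,3,4,6-Tetrachlorodibenzofuran",6.46,5.95,5.86,6.68,5.56,6.27,
"2,3,4,8-Tetrachlorodibenzofuran",6.70,6.19,5.84,5.55,5.38,5.70,
"1,3,6,8-Tetrachlorodibenzofuran",6.66,5.63,5.52,6.36,5.92,5.94,
"2,3,7,8-Tetrachlorodibenzofuran",7.39,6.96,6.54,7.18,6.84,6.86,
"1,2,4,8-Tetrachlorodibenzofuran",5.00,5.16,5.32,4.19,4.90,4.76,
"1,2,4,6,7-Pentachlorodibenzofuran",7.17,5.65,5.50,5.82,5.54,5.66,
"1,2,4,7,9-Pentachlorodibenzofuran",4.70,6.82,6.34,5.22,5.40,5.78,
"1,2,3,4,8-Pentachlorodibenzofuran",6.92,6.42,5.74,5.49,5.21,5.62,
"1,2,3,7,8-Pentachlorodibenzofuran",7.13,7.03,6.56,6.96,7.19,6.76,
"1,2,4,7,8-Pentachlorodibenzofuran",5.89,5.94,5.57,6.32,5.94,5.95,
"2,3,4,7,8-Pentachlorodibenzofuran",7.82,6.42,6.42,7.08,6.80,6.75,
"1,2,3,4,7,8-Hexachlorodibenzofuran",6.64,6.61,6.06,7.22,6.95,6.64,
"1,2,3,6,7,8-Hexachlorodibenzofuran",6.57,7.22,6.78,6.67,6.47,6.73,
"1,2,4,6,7,8-Hexachlorodibenzofuran",5.08,6.58,5.83,6.53,5.70,6.18,
"2,3,4,6,7,8-Hexachlorodibenzofuran",7.33,7.93,6.85,7.73,6.60,7.29,
"2,3,6,8-Tetrachlorodibenzofuran",6.66,5.39,5.23,5.58,5.42,5.41,
"1,2,3,6-Tetrachlorodibenzofuran",6.46,4.93,5.36,6.17,5.85,5.77,
"1,2,3,7-Tetrachlorodibenzofuran",6.96,6.93,6.57,7.00,7.22,6.79,
"1,3,4,7,8-Pentachlorodibenzofuran",6.70,6.82,6.59,6.60,6.53,6.60,
"2,3,4,7,9-Pentachlorodibenzofuran",6.70,6.54,6.34,7.29,6.99,6.82,
"1,2,3,7,9-Pentachlorodibenzofuran",6.40,6.32,6.40,6.69,6.94,6.55,
H,3.00,3.53,4.46,3.98,3.95,4.22,truncated_name
"2,3,4,7-Tetrachlorodibenzofuran",7.60,6.08,6.44,6.37,6.29,6.41,
"1,2,3,7-Tetrachlorodibenzofuran",6.96,6.97,6.59,7.00,7.17,6.80,duplicate_name
"1,3,4,7,8-Pentachlorodibenzofuran",6.70,6.84,6.58,6.62,6.52,6.60,duplicate_name
"2,3,4,7,9-Pentachlorodibenzofuran",6.70,6.52,6.36,7.23,6.96,6.80,duplicate_name
"1,2,3,7,9-Pentachlorodibenzofuran",6.40,6.38,6.41,6.68,6.94,6.55,duplicate_name
"1,2,4,6,8-Pentachlorodibenzofuran",5.51,5.81,5.61,3.30,4.80,4.46,
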