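treatment,year,replicate,pH,SP,TC,TN,TP,TK,NH4,NO3,AP,AK,CAT,INV,NAG,URE,ALP,GLS
NPK,2022,1,8.72,48.2,9.62,1.6,1.49,12.17,17.39,8.95,31.12,102.17,0.84,17.87,6.02,0.39,0.09,25.47
NPK,2022,2,8.72,48.2,9.62,1.6,1.49,12.17,17.39,8.95,31.12,102.17,0.84,17.87,6.02,0.39,0.09,25.47
NPK,2022,3,8.72,48.2,9.62,1.6,1.49,12.17,17.39,8.95,31.12,102.17,0.84,17.87,6.02,0.39,0.09,25.47
CM,2022,1,8.6,49.65,10.2,1.79,1.62,13.36,18.29,9.89,38.66,142.59,1.03,19.59,6.69,0.54,0.15,31.8
CM,2022,2,8.6,49.65,10.2,1.79,1.62,13.36,18.29,9.89,38.66,142.59,1.03,19.59,6.69,0.54,0.15,31.8
CM,2022,3,8.6,49.65,10.2,1.79,1.62,13.36,18.29,9.89,38.66,142.59,1.03,19.59,6.69,0.54,0.15,31.8
PM,2022,1,8.64,50.28,10.43,1.83,1.79,12.64,19.66,10.92,48.29,95.65,0.92,23.38,7.03,0.63,0.12,37.64
PM,2022,2,8.64,50.28,10.43,1.83,1.79,12.64,19.66,10.92,48.29,95.65,0.92,23.38,7.03,0.63,0.12,37.64
PM,2022,3,8.64,50.28,10.43,1.83,1.79,12.64,19.66,10.92,48.29,95.65,0.92,23.38,7.03,0.63,0.12,37.64
SM,2022,1,8.67,49.91,10.71,1.81,1.88,12.7,18.96,10.35,40.89,129.7,1.03,22.21,7.42,0.5,0.11,28.44
SM,2022,2,8.67,49.91,10.71,1.81,1.88,12.7,18.96,10.35,40.89,129.7,1.03,22.21,7.42,0.5,0.11,28.44
SM,2022,3,8.67,49.91,10.71,1.81,1.88,12.7,18.96,10.35,40.89,129.7,1.03,22.21,7.42,0.5,0.11,28.44
NPK,2023,1,8.29,47.71,9.55,1.63,1.53,12.37,17.69,10.15,35.88,101.16,0.91,18.26,6.46,0.48,0.09,28.16
NPK,2023,2,8.29,47.71,9.55,1.63,1.53,12.37,17.69,10.15,35.88,101.16,0.91,18.26,6.46,0.48,0.09,28.16
NPK,2023,3,8.29,47.71,9.55,1.63,1.53,12.37,17.69,10.15,35.88,101.16,0.91,18.26,6.46,0.48,0.09,28.16
CM,2023,1,8.03,49.95,10.22,1.83,1.74,13.63,18.76,11.37,44.91,129.8,1.25,20.06,7.42,0.69,0.16,35.58
CM,2023,2,8.03,49.95,10.22,1.83,1.74,13.63,18.76,11.37,44.91,129.8,1.25,20.06,7.42,0.69,0.16,35.58
CM,2023,3,8.03,49.95,10.22,1.83,1.74,13.63,18.76,11.37,44.91,129.8,1.25,20.06,7.42,0.69,0.16,35.58
PM,2023,1,8.14,51.33,10.53,1.9,1.9,13.28,20.33,12.87,56.77,87.41,1.03,25.12,7.82,0.9,0.14,43.33
PM,2023,2,8.14,51.33,10.53,1.9,1.9,13.28,20.33,12.87,56.77,87.41,1.03,25.12,7.82,0.9,0.14,43.33
PM,2023,3,8.14,51.33,10.53,1.9,1.9,13.28,20.33,12.87,56.77,87.41,1.03,25.12,7.82,0.9,0.14,43.33
SM,2023,1,8.16,50.35,10.9,1.87,2.04,13.33,19.47,11.93,47.98,121.56,1.16,23.05,8.29,0.62,0.12,31.89
SM,2023,2,8.16,50.35,10.9,1.87,2.04,13.33,19.47,11.93,47.98,121.56,1.16,23.05,8.29,0.62,0.12,31.89
SM,2023,3,8.16,50.35,10.9,1.87,2.04,13.33,19.47,11.93,47.98,121.56,1.16,23.05,8.29,0.62,0.12,31.89
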