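sample_id,origin,tp,abts,reducing_sugars,protein,fat,nhcs,c,n,s,ph
1,Legnica,12.33,168.5,27.6,22.38,9.64,56.10,45.09,3.58,0.105,4.05
2,Legnica,12.08,172.6,32.0,23.56,9.78,57.30,46.02,3.77,0.076,4.64
3,Stróże,12.54,223.1,41.0,25.00,7.58,57.51,46.13,4.00,0.112,4.55
4,Stróże,9.52,157.0,32.4,20.81,8.94,56.61,45.73,3.33,0.097,4.88
5,Sulęcin,11.46,178.6,29.6,24.13,10.20,58.11,46.65,3.86,0.061,4.66
6,Łódź,8.98,168.2,35.2,20.63,8.97,56.15,45.59,3.30,0.131,4.92
7,Malbork,7.91,149.2,42.2,17.69,8.95,56.04,45.87,2.83,0.103,4.59
8,Otmuchów,9.35,181.9,35.2,22.88,9.17,57.75,46.58,3.66,0.158,4.76
9,Otmuchów,8.11,160.7,36.4,19.75,7.89,56.22,45.63,3.16,0.125,4.96
10,Stróże,4.16,117.2,38.9,15.88,7.90,53.37,43.73,2.54,0.102,4.97
11,Sokołów Małopolski,13.01,235.3,42.8,25.63,7.76,57.98,46.52,4.10,0.162,4.74
12,Wadowice,7.69,167.0,39.6,16.94,7.84,55.95,45.34,2.71,0.118,5.59
13,Uścikowo,6.11,141.6,38.4,16.88,8.42,58.36,46.50,2.70,0.111,5.29
14,Malbork,9.41,160.8,40.8,15.69,7.87,56.66,45.92,2.51,0.180,5.29
15,Suchlica,7.12,152.9,44.8,26.19,8.38,57.69,46.75,4.19,0.202,4.54
16,Łódź,10.31,209.2,28.8,25.00,8.16,56.15,47.80,4.00,0.165,5.33
17,Legnica,9.70,180.7,39.2,21.88,11.16,58.72,44.73,3.50,0.143,4.84
18,Częstochowa,8.43,140.3,46.0,20.25,9.24,59.73,46.76,3.24,0.174,5.27
19,Częstochowa,10.61,208.6,34.7,25.50,7.56,55.56,46.13,4.08,0.165,5.25
20,Wrocław,7.80,155.7,36.3,21.06,8.66,58.46,45.10,3.37,0.145,4.96
21,Stróże,8.90,186.5,37.6,21.38,8.21,57.24,46.22,3.42,0.239,5.13
22,Wola Węgierska,10.32,172.7,37.9,21.13,8.26,55.93,46.86,3.38,0.172,4.86
23,Bielsko-Biała,9.84,190.6,37.9,21.75,8.04,57.37,46.05,3.48,0.123,4.81
24,Rogóż,8.15,169.8,37.0,20.00,10.01,57.45,46.46,3.20,0.160,4.83
25,Otmuchów,5.75,119.3,33.2,16.13,8.49,57.27,44.57,2.58,0.125,4.81
26,Wambierzyce,9.61,185.7,35.2,21.13,8.53,56.98,45.81,3.38,0.136,5.50
27,Kozaki,7.32,146.4,37.6,17.94,7.98,56.06,45.48,2.87,0.161,5.40
28,Byków,9.78,165.5,30.4,19.81,9.71,56.39,45.45,3.17,0.213,4.06
29,Byków,13.39,191.2,38.4,24.69,9.85,58.83,46.93,3.95,0.191,4.41
30,Kamienna Góra,14.57,264.8,40.8,28.81,8.25,59.37,47.47,4.61,0.192,5.80
31,mix1,13.18,193.8,27.2,23.94,9.07,58.10,46.42,3.83,0.204,6.30
32,mix2,13.92,210.8,23.2,27.63,12.28,58.92,46.72,4.42,0.228,4.74
33,mix3,11.86,203.1,29.2,27.50,11.15,59.55,47.60,4.40,0.189,4.98
34,mix4,12.84,196.3,25.6,25.13,11.98,59.31,47.32,4.02,0.227,5.14
35,mix5,12.92,205.2,44.0,14.88,8.39,55.72,45.46,2.38,0.130,5.09
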