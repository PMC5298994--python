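Name,TDB6e,ATSC5s,GATS5s,TDB8i,TDB10i,TDB6p,TDB6r,TDB6v,TDB5u,RotBtFrac,VP-6
Ethidium bromide,41.75,-0.13,0.67,1254.65,1816.65,8.32,1.82,1080.21,4.91,0.19,2.15
DAPI+2,45.31,1.50,0.77,1362.00,1733.37,8.26,1.87,1100.05,4.90,0.22,1.04
Evans blue,53.62,-311.14,1.25,1201.18,1460.62,8.61,2.29,1333.31,4.99,0.30,2.57
Hexidium iodide,42.18,2.62,0.66,1188.58,1515.93,8.51,1.85,1114.43,4.94,0.29,2.72
Methylene blue,45.98,1.91,0.77,1312.73,1773.06,9.33,2.00,1121.27,4.87,0.23,1.82
Procion orange MX2R,51.98,-37.82,1.07,1188.57,1451.99,10.12,2.49,1460.71,5.04,0.27,1.95
Propidium iodide,41.28,9.71,0.57,1171.03,1402.39,7.71,1.71,1005.28,4.68,0.35,3.15
Ethidium homodimer-2,41.16,15.42,0.56,1179.16,1418.41,7.96,1.76,1039.38,4.76,0.32,6.92
BBG,40.90,6.61,0.54,1103.96,1296.55,7.87,1.71,1018.14,4.80,0.34,3.36
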