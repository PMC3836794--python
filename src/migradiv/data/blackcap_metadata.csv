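code,name,n,lat,lon,direction,distance,breeding,ae,ae_se,ho,ho_se,he,he_se
Sv,"Sevilla, ES",8,37.65,-5.58,SW,short,False,3.79,0.40,0.65,0.06,0.76,0.02
Ub,"Uebersyren, LU",43,49.63,6.28,SW,intermediate,True,4.33,0.50,0.72,0.03,0.74,0.03
Fr_NW,"Freiburg, DE (NW migrants)",23,48.03,7.82,NW,intermediate,True,4.15,0.47,0.66,0.05,0.73,0.03
Fr_SW,"Freiburg, DE (SW migrants)",82,48.03,7.82,SW,intermediate,True,4.62,0.54,0.70,0.02,0.76,0.02
Wh,"Wilhelmshaven, DE",24,53.52,8.12,SW,long,True,4.17,0.40,0.60,0.03,0.75,0.02
Mn,"Muensingen, DE",25,48.40,10.00,SW,intermediate,True,4.32,0.56,0.72,0.03,0.74,0.03
Os,"Oslo, NO",25,59.84,10.86,SW,long,True,4.11,0.46,0.68,0.03,0.73,0.03
Kf,"Kefermarkt, AT",105,48.44,14.54,SE,intermediate,True,4.63,0.50,0.69,0.03,0.76,0.02
Vn,"Vienna, AT",35,48.22,16.28,SE,intermediate,True,4.39,0.50,0.72,0.02,0.75,0.03
Ry,"Rybachy, RU",51,55.15,20.85,SE,long,True,4.32,0.52,0.66,0.03,0.74,0.03
Bw,"Bialowieza, PL",61,52.70,23.87,SE,long,True,4.48,0.45,0.73,0.03,0.76,0.02
Km,"Kalimok, BG",20,44.00,26.26,SE,long,True,3.87,0.38,0.71,0.04,0.73,0.03
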