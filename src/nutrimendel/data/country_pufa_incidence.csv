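code,country,period,incidence_per_100k,AA,DHA,omega6_lcpufa,omega3_lcpufa,gdp_per_capita
BRA,Brazil,1965-1994,47.2,71.97,65.35,106.99,158.03,431.3
CAN,Canada,1995-1998,33.0,231.99,180.74,356.23,443.35,8590.8
CHL,Chile,2004-2017,13.4,113.12,126.64,164.82,255.50,3076.6
CRI,Costa Rica,1979-1981,48.2,59.00,49.29,84.85,129.73,355.0
HRV,Croatia,1980-1985,26.0,100.14,54.09,165.14,126.67,4852.2
DNK,Denmark,1995-2008,9.2,201.39,172.04,352.87,366.56,13333.0
FIN,Finland,2003,37.8,179.83,283.62,291.77,592.44,10497.5
DEU,Germany,1987-1989,19.0,187.32,131.59,325.37,314.24,2761.2
ISL,Iceland,1967,27.0,297.87,561.37,378.27,1278.49,1418.1
IND,India,1987-1988,58.5,14.70,29.26,20.41,65.78,98.1
IRL,Ireland,1974-1977,27.5,185.71,120.95,285.16,355.25,739.3
ITA,Italy,2008-2011,9.6,220.95,214.39,338.11,468.64,18728.4
JPN,Japan,1979-1980,21.0,89.70,384.11,120.07,682.04,563.6
NLD,Netherlands,1981-1997,22.3,164.43,123.68,267.52,297.9,3662.2
NZL,New Zealand,2014,6.3,294.28,242.54,410.68,630.07,17400.4
NOR,Norway,1982-1983,5.5,154.97,318.68,232.38,658.06,1721.4
KOR,Republic of Korea,2008-2017,50.0,137.70,339.12,198.58,978.261,9057.6
RUS,Russian Federation,2015,8.0,162.29,194.33,248.96,421.68,2665.8
ESP,Spain,1989-1990,19.0,157.49,263.78,234.63,525.39,1145.0
SWE,Sweden,1997-2006,13.0,188.92,229.14,305.55,503.14,14272.5
CHE,Switzerland,1977-2005,11.8,188.47,137.66,308.20,350.49,8953.3
UKR,Ukraine,1986-1997,11.0,149.60,114.19,248.40,261.74,1417.9
GBR,United Kingdom,1998-2005,4.1,201.51,165.01,311.62,403.32,7937.9
USA,United States,2007-2013,7.5,274.59,186.38,406.67,444.37,23478.6
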