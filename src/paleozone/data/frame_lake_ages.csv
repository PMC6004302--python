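depth,year_ad,sed_rate_cm_yr,sed_rate_ash_cm_yr,hiatus_below_label
0.0,2012.0,1.5,0.34,
1.0,2011.33,0.48,0.34,
2.0,2009.23,0.71,0.34,
2.5,2008.53,0.99,0.34,
3.0,2008.02,1.13,0.34,
3.5,2007.58,1.18,0.34,
4.0,2007.16,0.75,0.34,
4.5,2006.48,0.52,0.34,
5.0,2005.52,0.2,0.34,
6.0,2000.47,0.43,0.34,
7.0,1998.12,0.43,0.34,
8.0,1995.81,0.45,0.34,
9.0,1993.6,0.6,0.34,
10.0,1991.94,0.45,0.34,
11.0,1989.7,0.36,0.34,
12.0,1986.96,0.24,0.34,
13.0,1982.74,0.24,0.34,
14.0,1978.64,0.24,0.34,
15.0,1974.47,0.17,0.34,
16.0,1968.58,0.17,0.34,
17.0,1962.69,0.17,0.34,">7,000 BP"
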