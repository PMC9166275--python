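year,mean,se,ci_lower,ci_upper
2014,254162,105725,116160,556116
2015,408749,161343,193887,861719
2016,814855,331218,378635,1753838
2017,1060687,353234,562735,2002824
2018,1319939,252108,910806,1912854
2019,103020,42925,47027,225683
2020,25259,9485,12395,51473
2021,87751,34706,41568,185250
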