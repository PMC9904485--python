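site,pct_census1,pct_census3,pct_increase,rate_m_per_yr
edoro1,11.4,15.1,33.2,0.44
lenda1,65.6,68.0,3.52,0.27
lenda2,82.1,82.4,0.35,0.034
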