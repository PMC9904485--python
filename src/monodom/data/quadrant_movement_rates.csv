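site,patch,quadrant,ci_low,rate,ci_high,significant,expected_sign,expansion
edoro1,1,N,-0.29,-0.15,-0.01,y,+,n
edoro1,1,S,-0.38,-0.24,-0.10,y,-,y
edoro1,1,W,-0.56,-0.17,0.21,n,-,y
edoro1,1,E,-0.13,0.17,0.46,n,+,y
edoro1,2,N,0.69,0.90,1.08,y,+,y
edoro1,2,S,-1.17,-0.94,-0.69,y,-,y
edoro1,2,W,-1.07,-0.87,-0.64,y,-,y
edoro1,2,E,1.25,1.42,1.59,y,+,y
lenda1,1,N,-0.29,0.05,0.37,n,+,y
lenda1,1,S,-0.78,-0.29,0.21,n,-,y
lenda1,1,W,-0.53,0.00,0.55,n,-,n
lenda1,1,E,-0.25,0.04,0.31,n,+,y
lenda2,1,N,0.43,1.27,2.12,y,+,y
lenda2,1,S,-1.48,-0.02,1.44,n,-,y
lenda2,1,W,-0.01,0.24,0.49,n,-,n
lenda2,1,E,-1.93,-1.21,-0.52,y,+,n
lenda2,2,N,-0.64,-0.32,0.01,n,+,n
lenda2,2,S,-0.70,-0.52,-0.31,y,-,y
lenda2,2,W,-1.59,-1.16,-0.77,y,-,y
lenda2,2,E,-0.57,0.01,0.59,n,+,y
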