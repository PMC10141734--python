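fly_origin,host_origin,n_flies,n_hosts,observed,possible,printed_pct,printed_p
N,N,6,21,19,126,15.08,0.067
N,E,6,29,15,174,8.93,<0.001
E,N,10,21,40,210,19.05,0.064
E,E,10,29,68,280,24.28,0.012
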