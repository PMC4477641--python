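sample,n_repeats,phasing,n_trajectories,amplitude_nm,uncertainty_nm
6An0,0,none,3496,149.7,0.2
6An1P,1,in_phase,2728,149.1,0.2
6An2P,2,in_phase,2354,149.7,0.2
6An3P,3,in_phase,2904,149.6,0.2
6An4P,4,in_phase,2604,146.5,0.2
6An6P,6,in_phase,348,145.2,0.4
6An7P,7,in_phase,431,140.4,0.4
6An4O,4,opposed,2990,151.2,0.2
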