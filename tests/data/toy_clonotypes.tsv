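Count	CDR3.amino.acid.sequence	V.segments	J.segments
12	CASSF	TRAV6-7,TRAV6-6	TRAJ33
5	CAVSNCNTGKLIF	TRAV1	TRAJ33
2	CALSGGGNYKLTF	TRAV2	TRAJ12
3	CALSGGSNYKLTF	TRAV3	TRAJ12
10	CAV*NLNTGKLIF	TRAV4	TRAJ21
1	CAVRF	TRAV5	TRAJ21
7	CAVS_LNTGKLIF	TRAV5	TRAJ21
3	CASSF	TRAV6-7	TRAJ33
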