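sample_id	group	age	sex
S01	SR40	40	F
S02	SR40	40	M
S03	SR40	40	M
S04	SR50	50	F
S05	SR50	50	M
S06	SR50	50	M
S07	SR60	60	F
S08	SR60	60	M
S09	SR60	60	M
S10	SR70	70	F
S11	SR70	70	M
S12	SR70	70	M
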