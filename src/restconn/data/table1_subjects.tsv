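subject_id	ftnd	co_abs_ppm	co_sat_ppm
001	5	14	28
002	6	15	42
003	8	11	24
004	6	13	26
005	6	12	25
006	6	11	26
007	6	7	21
008	5	8	17
009	7	8	21
010	6	6	15
011	6	11	21
012	8	15	42
013	8	5	26
014	6	4	11
015	6	13	23
016	7	12	26
017	6	7	19
018	6	6	13
019	5	5	13
020	5	7	17
021	6	12	24
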