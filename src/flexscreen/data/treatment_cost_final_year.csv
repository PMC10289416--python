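band,stage_0,stage_1,stage_2,stage_3,stage_4
46-49,38100,33100,38900,55400,29200
50-54,31500,26600,32400,48900,22700
55-59,27700,22800,28500,45000,18900
60-64,24600,19700,25500,42000,15800
65-69,26100,21200,26900,43400,17300
70-74,16900,11900,17700,34200,8000
75+,12300,7300,13100,29600,3400
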