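band,stage_0,stage_1,stage_2,stage_3,stage_4
46-49,4000,2400,3300,6400,2000
50-54,3700,2000,2900,6000,1600
55-59,3400,1700,2600,5700,1300
60-64,3200,1500,2400,5500,1100
65-69,3400,1800,2600,5700,1300
70-74,3200,1500,2400,5500,1100
75+,3000,1300,2200,5300,900
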