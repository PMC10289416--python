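band,stage_0,stage_1,stage_2,stage_3,stage_4
46-49,24800,20400,28400,33300,15300
50-54,22400,18000,26100,30900,12900
55-59,23300,18800,26900,31800,13800
60-64,20900,16400,24500,29400,11300
65-69,21100,16600,24700,29600,11600
70-74,18700,14300,22300,27200,9200
75+,14200,9800,17800,22700,4700
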