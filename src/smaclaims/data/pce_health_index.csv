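year,value
2019,110.5
2020,112.7
2021,115.0
2022,117.8
2023,120.6
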