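year,index
2016,86.0
2017,87.7
2018,89.2
2019,89.8
2020,89.5
2021,92.3
2022,100.1
2023,103.6
2024,106.6
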