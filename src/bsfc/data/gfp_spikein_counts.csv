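day,concentration_per_ul,volume_ul,expected_count,detected_count
1,7.08,135,956,944
2,3.13,160,500,468
3,5.56,180,1000,997
4,8.13,124,1008,933
5,12.28,135,1657,1648
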