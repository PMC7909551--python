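# Synthetic example MIC frequency distribution (wild-type-like shape).
# Constructed for tests and demonstrations; NOT surveillance data.
mic,frequency
0.5,0.01
1.0,0.06
2.0,0.30
4.0,0.40
8.0,0.15
16.0,0.05
32.0,0.03
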