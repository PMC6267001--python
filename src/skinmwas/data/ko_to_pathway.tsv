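# Pathway	KO
PW_BCAA_BIOSYNTH	K01652
PW_BCAA_BIOSYNTH	K01653
PW_BCAA_BIOSYNTH	K00053
PW_BCAA_BIOSYNTH	K01687
PW_BCAA_BIOSYNTH	K00826
PW_BCAA_DEGRAD	K00826
PW_BCAA_DEGRAD	K00166
PW_BCAA_DEGRAD	K00167
PW_BCAA_DEGRAD	K09699
PW_BCAA_DEGRAD	K00253
PW_PYRUVATE	K00161
PW_PYRUVATE	K00162
PW_PYRUVATE	K00627
PW_PYRUVATE	K00382
PW_PYRUVATE	K01895
PW_GLYCOLYSIS	K00134
PW_GLYCOLYSIS	K00927
PW_GLYCOLYSIS	K01689
PW_GLYCOLYSIS	K01834
PW_SULFUR	K01760
PW_SULFUR	K00640
PW_SULFUR	K01738
PW_FA_BIOSYNTH	K00059
PW_FA_BIOSYNTH	K00645
PW_FA_BIOSYNTH	K02160
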