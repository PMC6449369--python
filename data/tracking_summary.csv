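individual,n_dives,tracking_days
GS01,27055,104
GS02,33291,162
GS03,17778,173
GS04,27888,138
GS05,26114,179
GS06,50879,146
GS07,20546,75
GS08,29589,103
GS09,24112,74
GS10,29952,89
GS11,16691,73
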