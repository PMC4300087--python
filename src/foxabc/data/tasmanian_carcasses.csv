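year,type,count
2001,hunter,1
2003,road,1
2005,road,1
2006,road,1
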