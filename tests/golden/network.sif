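CDC42	pp	CTNNB1
CDC42	pp	ERBB2
CDC42	pp	MAPK3
CDC42	pp	PIK3CA
CTNNB1	pp	ERBB2
CTNNB1	pp	RHOA
ERBB2	pp	MYC
MAPK3	pp	MYC
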