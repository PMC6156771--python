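study_id,ref,comp,loghr_os,se_os,loghr_pfs,se_pfs
CCI-NOV22,P,M+P,-0.1800,0.1650,-0.9200,0.2000
CALGB9182,P,M+P,-0.0500,0.1445,-0.2200,0.1450
Berry2002,P,M+P,-0.0888,0.1850,-0.4073,0.1750
TAX327,M+P,D+P,-0.27444,0.10508,,
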