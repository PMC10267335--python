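genotype,condition,total_isc,baseline_isc,above_baseline
Q1291H/F508del,IVA,3.30,3.45,
Q1291H/F508del,ELX/TEZ,6.00,3.45,
Q1291H/F508del,ETI,5.73,3.45,
G551D/F508del,IVA,3.23,,1.42
G551D/F508del,ELX/TEZ,9.53,,7.72
G551D/F508del,ETI,10.53,,8.72
F508del/F508del,ELX/TEZ,20.24,,18.80
F508del/F508del,ETI,27.19,,25.75
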