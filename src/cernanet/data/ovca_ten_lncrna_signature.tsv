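lncrna	coefficient
AC005562.1	5.303e-02
AC074117.10	-8.968e-02
AC105760.2	6.192e-01
EPB41L4A-AS1	1.088e-02
MALAT1	1.182e-06
MCM3AP-AS1	4.516e-02
MEG8	-1.121e-01
RP11-220I1.1	-1.045e-02
RP11-429J17.2	5.753e-02
RP11-618G20.1	-3.291
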