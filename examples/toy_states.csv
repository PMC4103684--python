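gene,stage,state
Otx2,E8.5,ON
Otx2,E10.5,ON
Otx2,E12.5,ON
Gbx2,E8.5,ON
Gbx2,E10.5,ON
Gbx2,E12.5,ON
Fgf8,E8.5,OFF
Fgf8,E10.5,OFF
Fgf8,E12.5,OFF
Wnt1,E8.5,ON
Wnt1,E10.5,ON
Wnt1,E12.5,ON
En,E8.5,OFF
En,E10.5,OFF
En,E12.5,OFF
Pax,E8.5,OFF
Pax,E10.5,OFF
Pax,E12.5,OFF
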