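mirna,gene,tool,score
miR-705,En,TargetScan,0.7
miR-705,En,PicTar,0.75
miR-705,En,miRNAMAP,0.8
miR-705,En,TargetSpy,0.85
miR-705,Pax,TargetScan,0.72
miR-705,Pax,PicTar,0.77
miR-705,Pax,miRNAMAP,0.82
miR-709,En,TargetScan,0.8
miR-709,En,PicTar,0.85
miR-709,En,miRNAMAP,0.9
miR-709,En,TargetSpy,0.95
miR-709,En,DIANA,1.0
miR-709,Fgf8,PicTar,0.85
miR-709,Fgf8,miRNAMAP,0.9
miR-709,Fgf8,TargetSpy,0.95
miR-101,Pax,TargetScan,0.4
miR-101,Pax,PicTar,0.45
miR-101,Pax,miRNAMAP,0.5
miR-101,Fgf8,miRNAMAP,0.35
miR-101,Fgf8,TargetSpy,0.4
miR-101,Fgf8,DIANA,0.45
miR-202,En,TargetScan,0.2
miR-202,En,PicTar,0.25
miR-202,En,miRNAMAP,0.3
miR-202,Pax,TargetScan,0.25
miR-202,Pax,PicTar,0.3
miR-202,Pax,miRNAMAP,0.35
miR-300,Otx2,TargetScan,0.9
miR-300,Otx2,PicTar,0.95
miR-300,Otx2,miRNAMAP,1.0
miR-300,Otx2,TargetSpy,1.05
miR-300,En,TargetScan,0.9
miR-300,En,PicTar,0.95
miR-300,En,miRNAMAP,1.0
miR-301,En,TargetScan,0.6
miR-301,En,PicTar,0.65
miR-302,Fgf8,TargetScan,0.55
miR-302,Fgf8,PicTar,0.6
miR-302,Fgf8,miRNAMAP,0.65
miR-303,Wnt1,TargetScan,0.95
miR-303,Wnt1,PicTar,1.0
miR-303,Wnt1,miRNAMAP,1.05
miR-303,Wnt1,TargetSpy,1.1
miR-303,Wnt1,DIANA,1.15
miR-303,Pax,TargetScan,0.9
miR-303,Pax,PicTar,0.95
miR-303,Pax,miRNAMAP,1.0
miR-303,En,TargetScan,0.9
miR-303,En,PicTar,0.95
miR-303,En,miRNAMAP,1.0
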