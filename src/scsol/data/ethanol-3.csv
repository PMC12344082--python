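system,T_K,P_MPa,rho_kg_m3,y2,y3,sd
ethanol-3,308,12,768.4,0.0002259,0.03,7e-07
ethanol-3,308,15,816.1,0.0002456,0.03,9e-07
ethanol-3,308,18,848.9,0.0002759,0.03,1e-06
ethanol-3,308,21,874.4,0.0002964,0.03,1e-06
ethanol-3,308,24,895.5,0.0003405,0.03,1.3e-06
ethanol-3,308,27,913.7,0.0003793,0.03,1.1e-06
ethanol-3,308,30,929.7,0.0004677,0.03,1.2e-06
ethanol-3,318,12,659.7,0.0002001,0.03,7e-07
ethanol-3,318,15,743.2,0.0003044,0.03,8e-07
ethanol-3,318,18,790.2,0.0003766,0.03,1e-06
ethanol-3,318,21,823.7,0.000451,0.03,1.1e-06
ethanol-3,318,24,850.1,0.0004819,0.03,1.2e-06
ethanol-3,318,27,872,0.0005187,0.03,1.6e-06
ethanol-3,318,30,890.9,0.0005803,0.03,1.9e-06
ethanol-3,328,12,506.9,0.0001872,0.03,5e-07
ethanol-3,328,15,654.9,0.0003097,0.03,8e-07
ethanol-3,328,18,724.1,0.0004387,0.03,1.1e-06
ethanol-3,328,21,768.7,0.0005789,0.03,1.4e-06
ethanol-3,328,24,801.9,0.0006392,0.03,1.5e-06
ethanol-3,328,27,828.5,0.0006953,0.03,1.7e-06
ethanol-3,328,30,850.8,0.0007361,0.03,1.9e-06
ethanol-3,338,12,384.2,0.0001225,0.03,3e-07
ethanol-3,338,15,555.2,0.000266,0.03,9e-07
ethanol-3,338,18,651.2,0.0005165,0.03,1.4e-06
ethanol-3,338,21,709.7,0.0006298,0.03,1.6e-06
ethanol-3,338,24,751.2,0.0007149,0.03,1.9e-06
ethanol-3,338,27,783.3,0.0008166,0.03,2.1e-06
ethanol-3,338,30,809.6,0.0008979,0.03,2.3e-06
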