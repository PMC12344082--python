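system,T_K,P_MPa,rho_kg_m3,y2,y3,sd
ethanol-1,308,12,768.4,7.66e-05,0.01,2.6e-06
ethanol-1,308,15,816.1,7.68e-05,0.01,2.7e-06
ethanol-1,308,18,848.9,9.5e-05,0.01,3.2e-06
ethanol-1,308,21,874.4,0.0001038,0.01,3.5e-06
ethanol-1,308,24,895.5,0.0001216,0.01,4.1e-06
ethanol-1,308,27,913.7,0.0001377,0.01,4.7e-06
ethanol-1,308,30,929.7,0.0001423,0.01,4.8e-06
ethanol-1,318,12,659.7,7.01e-05,0.01,2.4e-06
ethanol-1,318,15,743.2,0.0001065,0.01,3.6e-06
ethanol-1,318,18,790.2,0.0001318,0.01,4.5e-06
ethanol-1,318,21,823.7,0.0001578,0.01,5.3e-06
ethanol-1,318,24,850.1,0.0001687,0.01,5.7e-06
ethanol-1,318,27,872,0.0001815,0.01,6.1e-06
ethanol-1,318,30,890.9,0.0002031,0.01,6.9e-06
ethanol-1,328,12,506.9,6.22e-05,0.01,2.1e-06
ethanol-1,328,15,654.9,9.14e-05,0.01,3.1e-06
ethanol-1,328,18,724.1,0.0001536,0.01,5.2e-06
ethanol-1,328,21,768.7,0.0002026,0.01,6.9e-06
ethanol-1,328,24,801.9,0.0002237,0.01,7.6e-06
ethanol-1,328,27,828.5,0.0002434,0.01,8.2e-06
ethanol-1,328,30,850.8,0.0002558,0.01,8.7e-06
ethanol-1,338,12,384.2,4.05e-05,0.01,1.3e-06
ethanol-1,338,15,555.2,9.25e-05,0.01,3.1e-06
ethanol-1,338,18,651.2,0.0001808,0.01,6.1e-06
ethanol-1,338,21,709.7,0.0002204,0.01,7.5e-06
ethanol-1,338,24,751.2,0.0002502,0.01,8.5e-06
ethanol-1,338,27,783.3,0.0002858,0.01,9.7e-06
ethanol-1,338,30,809.6,0.0003143,0.01,1.07e-05
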