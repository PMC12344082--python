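system,T_K,P_MPa,rho_kg_m3,y2,y3,sd
binary,308,12,768.4,2.38e-05,0,9e-07
binary,308,15,816.1,2.9e-05,0,1.1e-06
binary,308,18,848.9,3.85e-05,0,1.5e-06
binary,308,21,874.4,4.34e-05,0,1.7e-06
binary,308,24,895.5,5.29e-05,0,2.1e-06
binary,308,27,913.7,6.24e-05,0,2.5e-06
binary,308,30,929.7,7.95e-05,0,3.2e-06
binary,318,12,659.7,1.79e-05,0,7e-07
binary,318,15,743.2,3.23e-05,0,1.3e-06
binary,318,18,790.2,4.39e-05,0,1.7e-06
binary,318,21,823.7,5.77e-05,0,2.3e-06
binary,318,24,850.1,6.97e-05,0,2.8e-06
binary,318,27,872,7.59e-05,0,3e-06
binary,318,30,890.9,8.63e-05,0,3.4e-06
binary,328,12,506.9,1.48e-05,0,6e-07
binary,328,15,654.9,2.73e-05,0,1.1e-06
binary,328,18,724.1,4.84e-05,0,1.9e-06
binary,328,21,768.7,6.88e-05,0,2.7e-06
binary,328,24,801.9,7.78e-05,0,3.1e-06
binary,328,27,828.5,8.96e-05,0,3.6e-06
binary,328,30,850.8,9.75e-05,0,3.9e-06
binary,338,12,384.2,7.8e-06,0,3e-07
binary,338,15,555.2,1.97e-05,0,8e-07
binary,338,18,651.2,5.23e-05,0,2.1e-06
binary,338,21,709.7,7.24e-05,0,2.9e-06
binary,338,24,751.2,8.45e-05,0,3.4e-06
binary,338,27,783.3,9.81e-05,0,3.9e-06
binary,338,30,809.6,0.0001082,0,4.3e-06
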