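perspective,age,ly_pd,ly_hd,qaly_pd,qaly_hd,cost_pd,cost_hd,cost_per_ly_pd,cost_per_ly_hd,icer
government,20,9.85,11.84,6.43,8.19,90204,132084,9158,11156,23796
government,30,8.42,10.37,5.53,7.22,76613,114911,9099,11081,22662
government,40,6.71,8.36,4.46,5.91,60255,91366,8980,10929,21456
government,50,5.40,6.80,3.63,4.87,47873,73243,8865,10771,20460
government,60,4.32,5.49,2.94,3.99,37837,58243,8759,10609,19434
societal,20,9.85,11.84,6.43,8.19,96355,166600,9782,14071,39912
societal,30,8.42,10.37,5.53,7.22,81713,144894,9705,13972,37385
societal,40,6.71,8.36,4.46,5.91,63993,115143,9537,13773,35276
societal,50,5.40,6.80,3.63,4.87,50613,92251,9373,13566,33579
societal,60,4.32,5.49,2.94,3.99,39802,73311,9213,13353,31913
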