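sample_id,group,Pb,Cu,Zn,Ni,Cr,Mn,Fe
F1,A1,73.59,8.96,285.53,18.56,97.99,20946,275290
F2,A1,77.97,12.05,324.68,20.63,118.34,27401,316228
F3,A1,66.88,10.66,284.88,21.46,98.64,22623,271653
F4,A1,68.63,9.58,270.08,17.30,94.80,21822,262931
F5,A2,79.54,8.93,294.38,18.62,100.68,23564,295772
F6,A2,84.95,10.94,354.65,23.54,124.21,26687,351489
F7,A2,81.16,8.21,291.52,19.87,103.16,22612,299793
F8,A2,70.98,9.32,272.12,18.46,96.68,18372,254801
F9,A3,20.23,9.79,285.32,17.34,75.21,31969,214190
F10,A3,26.49,5.85,314.02,17.80,75.85,30146,265075
F11,A3,22.78,7.26,285.53,15.73,67.49,28506,230251
F12,A3,23.29,6.43,260.59,16.23,64.42,23923,227743
F13,B1,78.14,170.93,296.29,28.62,129.51,24550,236659
F14,B1,92.55,149.69,321.30,32.81,143.19,23373,252336
F15,B1,101.16,169.23,363.04,37.05,161.62,26408,285112
F16,B1,55.70,234.50,282.54,23.95,114.38,29909,234914
F17,B2,53.62,53.58,259.42,21.65,127.81,13362,216780
F18,B2,51.34,35.10,284.85,22.70,135.40,14640,222107
F19,B2,56.74,73.16,236.11,20.33,119.09,12112,211485
F20,B2,58.94,69.62,244.35,23.65,123.15,12088,213452
F21,C,64.22,12.51,291.23,18.21,103.32,25574,288543
F22,C,69.14,10.89,273.46,17.91,101.55,23376,267940
F23,C,60.71,11.43,272.88,16.73,95.03,24795,268322
F24,C,66.23,10.26,281.33,19.51,100.44,22248,277981
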