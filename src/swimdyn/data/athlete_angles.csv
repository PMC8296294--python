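athlete,right_knee,right_thigh,right_calf,finger_spread,stroke
S1,66.15,-47.26,-161.27,15,breaststroke
S2,50.68,-55.83,-185.41,30,freestyle
S3,64.23,-38.81,-152.11,25,breaststroke
S4,53.17,-45.36,-172.83,20,backstroke
S5,52.07,-43.58,-180.37,25,butterfly
S6,65.29,-46.73,-163.78,20,freestyle
S7,67.82,-45.69,-171.89,30,breaststroke
S8,53.94,-39.51,-164.15,25,breaststroke
S9,51.21,-43.83,-168.24,25,backstroke
S10,63.44,-52.18,-158.92,15,butterfly
S11,59.81,-51.72,-175.45,30,breaststroke
S12,64.35,-47.91,-165.71,20,backstroke
S13,56.99,-41.84,-149.16,25,freestyle
S14,58.84,-49.93,-163.32,30,freestyle
S15,66.13,-48.16,-179.27,25,breaststroke
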