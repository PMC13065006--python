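name,mass_fraction,com_fraction,gyration_x,gyration_y,gyration_z,limb_group
head_trunk,0.3923,0.4800,0.3720,0.3470,0.1910,trunk
pelvis,0.1117,0.6115,0.6150,0.5510,0.5870,trunk
thigh_r,0.1416,0.4095,0.3290,0.3290,0.1490,legs
thigh_l,0.1416,0.4095,0.3290,0.3290,0.1490,legs
shank_r,0.0433,0.4395,0.2510,0.2460,0.1020,legs
shank_l,0.0433,0.4395,0.2510,0.2460,0.1020,legs
foot_r,0.0137,0.4415,0.2570,0.2450,0.1240,legs
foot_l,0.0137,0.4415,0.2570,0.2450,0.1240,legs
upper_arm_r,0.0271,0.5772,0.2850,0.2690,0.1580,arms
upper_arm_l,0.0271,0.5772,0.2850,0.2690,0.1580,arms
forearm_r,0.0162,0.4574,0.2760,0.2650,0.1210,arms
forearm_l,0.0162,0.4574,0.2760,0.2650,0.1210,arms
hand_r,0.0061,0.7900,0.6280,0.5130,0.4010,arms
hand_l,0.0061,0.7900,0.6280,0.5130,0.4010,arms
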