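name,mass_fraction,com_fraction,gyration_x,gyration_y,gyration_z,limb_group
head_trunk,0.3678,0.4720,0.3710,0.3480,0.1940,trunk
pelvis,0.1247,0.4920,0.4330,0.4020,0.4440,trunk
thigh_r,0.1478,0.3612,0.3690,0.3640,0.1620,legs
thigh_l,0.1478,0.3612,0.3690,0.3640,0.1620,legs
shank_r,0.0481,0.4416,0.2710,0.2670,0.0930,legs
shank_l,0.0481,0.4416,0.2710,0.2670,0.0930,legs
foot_r,0.0129,0.4014,0.2990,0.2790,0.1390,legs
foot_l,0.0129,0.4014,0.2990,0.2790,0.1390,legs
upper_arm_r,0.0255,0.5754,0.2780,0.2600,0.1480,arms
upper_arm_l,0.0255,0.5754,0.2780,0.2600,0.1480,arms
forearm_r,0.0138,0.4559,0.2610,0.2570,0.0940,arms
forearm_l,0.0138,0.4559,0.2610,0.2570,0.0940,arms
hand_r,0.0056,0.7474,0.5310,0.4540,0.3350,arms
hand_l,0.0056,0.7474,0.5310,0.4540,0.3350,arms
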