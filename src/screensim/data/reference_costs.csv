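arm_id,label,hours_total,total_cost_gbp
1,Comparator A,234.08,7052.72
2,Comparator B,223.18,6724.53
3,Comparator C,158.45,4774.01
4,Intervention A,150.03,4520.48
5,Intervention B,146.71,4420.50
6,Intervention C,184.67,5564.24
7,Intervention D,168.92,5089.56
8,Intervention E,128.57,3873.71
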