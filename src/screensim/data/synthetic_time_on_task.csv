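arm_id,search_hours_per_week,dedup_hours_per_week,screen_hours_per_100
1,4.0,6.0,2.205455
2,4.0,6.0,2.193772
3,4.0,6.0,2.080991
4,4.0,6.0,1.804954
5,4.0,6.0,1.828792
6,0.0,2.0,2.104216
7,0.0,2.0,2.097771
8,0.0,2.0,2.599612
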