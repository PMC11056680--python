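arm_id,label,screened,includes,gold_total,search_hours_per_week,dedup_hours_per_week,screen_hours_per_100
1,Comparator A,8800,3520,4240,4.0,6.0,2.205455
2,Comparator B,8350,3340,4240,4.0,6.0,2.193772
3,Comparator C,5692,2277,4240,4.0,6.0,2.080991
4,Intervention A,6096,3353,4240,4.0,6.0,1.804954
5,Intervention B,5835,3326,4240,4.0,6.0,1.828792
6,Intervention C,8396,4198,4240,0.0,2.0,2.104216
7,Intervention D,7671,3989,4240,0.0,2.0,2.097771
8,Intervention E,4638,3989,4240,0.0,2.0,2.599612
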