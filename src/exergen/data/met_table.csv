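activity,youth_met,adult_met
aerobics,7.5,7.3
athletics,8.0,8.0
badminton,5.5,5.5
ballet,5.0,5.0
baseball,5.0,5.0
basketball,8.0,6.5
climbing,8.0,8.0
cycling_sport,8.0,7.5
dancing,5.5,5.0
field_hockey,7.8,7.8
fitness,6.0,5.0
golf,4.5,4.8
gymnastics,4.0,3.8
handball,8.0,8.0
hiking,4.5,6.0
horse_riding,4.0,5.5
ice_skating,6.5,7.0
inline_skating,7.5,7.5
jogging,7.0,7.0
judo,10.0,10.3
karate,10.0,10.3
korfball,8.0,7.0
rowing,7.0,7.0
running,8.0,8.3
soccer,8.0,7.0
squash,12.0,12.0
swimming,7.0,6.0
table_tennis,4.0,4.0
tennis,7.3,7.3
volleyball,4.5,4.0
water_polo,10.0,10.0
weight_training,4.0,3.5
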