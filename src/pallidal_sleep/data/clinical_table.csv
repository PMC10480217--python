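subject_id,diagnosis,nights,disease_duration,psqi,rbdsq,dystonia_subtype,motor_off,motor_on
PD-1,PD,1,20,16,11,,46,28
PD-2,PD,1,7,15,10,,26,11
PD-3,PD,1,6,9,2,,53,23
PD-4,PD,1,6,13,5,,33,21
PD-5,PD,1,5,6,1,,29,15
PD-6,PD,1,8,9,1,,45,31
PD-7,PD,2,10,13,7,,69,31
PD-8,PD,2,6,6,1,,71,32
PD-9,PD,2,12,15,2,,54,18
PD-10,PD,1,9,12,12,,67,32
PD-11,PD,1,7,5,1,,45,23
PD-12,PD,2,8,17,13,,66,37
Dyst-1,dystonia,2,2,5,,C,20,
Dyst-2,dystonia,2,3,10,,M,8,
Dyst-3,dystonia,1,5,9,,M,7,
Dyst-4,dystonia,2,5,9,,M,23,
Dyst-5,dystonia,1,4,6,,M,6,
Dyst-6,dystonia,1,4,1,,C,28,
Dyst-7,dystonia,1,3,19,,M,12,
Dyst-8,dystonia,1,5,14,,M,13,
Dyst-9,dystonia,1,7,5,,M,16,
Dyst-10,dystonia,2,3,3,,C,32,
Dyst-11,dystonia,1,15,11,,M,18,
Dyst-12,dystonia,1,15,1,,M,7,
Dyst-13,dystonia,1,4,5,,C,22,
Dyst-14,dystonia,1,3,3,,M,9,
Dyst-15,dystonia,1,5,11,,M,15,
Dyst-16,dystonia,1,6,7,,C,38,
Dyst-17,dystonia,1,7,6,,M,13,
Dyst-18,dystonia,1,3,6,,M,16,
Dyst-19,dystonia,1,6,10,,C,24,
Dyst-20,dystonia,1,2,6,,C,17,
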