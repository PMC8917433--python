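category,motivation,consequence,neither
Cancer,15,4,16
Cardiovascular,1,1,3
Cognitive,5,3,19
Death,4,7,79
Dermatological,0,0,4
Gastrointestinal,6,1,22
Immune System,2,2,31
Injury,1,5,49
Mental health,89,19,172
Neurological,18,40,102
Other,33,7,84
Pain,28,3,78
Poisoning,2,6,16
Pregnancy or in utero,2,2,10
Respiratory,0,17,30
Stress,17,1,20
Weight,0,0,16
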