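category,example_keywords,n,pct_printed
Cancer,cancer|tumor|malignant,13834,3.92
Cardiovascular,stroke|heart attack|blood pressure,1810,0.52
Cognitive,unconscious|attention,8807,2.49
Death,die|kill|lost life,31590,8.95
Dermatological,itchy|acne|blister,1557,0.44
Gastrointestinal,belly|belch|vomit|puke,10434,2.95
Immune System,flu|common cold|allergy,12229,3.46
Injury,injury|rupture|wound|bruise,19490,5.52
Mental health,ptsd|adhd|jittery,100155,28.34
Neurological,coma|dizzy|lightheaded,56347,15.95
Other,anemia|jaundice|mumps,44111,12.48
Pain,painful|achy|cramping,38335,10.85
Poisoning,toxic|poisonous|noxious,8345,2.36
Pregnancy or in utero,pregnant|preggers|miscarriage,4760,1.35
Respiratory,cough|wheeze|black lung,16616,4.70
Stress,stressed|cortisol,13372,3.78
Weight,fat|obese|weight|stoutness,5888,1.67
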