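dimension,level,decrement
mobility,2,0.05
mobility,3,0.08
mobility,4,0.16
mobility,5,0.25
self_care,2,0.04
self_care,3,0.07
self_care,4,0.14
self_care,5,0.21
usual_activities,2,0.03
usual_activities,3,0.06
usual_activities,4,0.11
usual_activities,5,0.17
pain_discomfort,2,0.05
pain_discomfort,3,0.09
pain_discomfort,4,0.16
pain_discomfort,5,0.213
anxiety_depression,2,0.04
anxiety_depression,3,0.08
anxiety_depression,4,0.14
anxiety_depression,5,0.182
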