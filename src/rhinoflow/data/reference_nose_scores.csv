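# Per-subject NOSE scores of the eight-subject reference septoturbinoplasty
# cohort (0-20 instrument; higher = worse obstruction); postoperative scores
# at three months.  good_response marks the S1-S3 subgroup whose improvement
# was significantly larger than the rest.
subject,nose_pre,nose_post,nose_improvement,good_response
S1,18,0,18,True
S2,15,0,15,True
S3,17,3,14,True
S4,10,0,10,False
S5,20,12,8,False
S6,13,5,8,False
S7,9,3,6,False
S8,13,9,4,False
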