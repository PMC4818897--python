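case,sex,age,flexion_pre,extension_pre,arc_pre,cuts,surgery,flexion_post,extension_post,arc_post
1,F,68,100,-30,70,-,arthroscopic,140,0,140
2,M,65,108,-45,63,+,open,130,-15,115
3,M,52,125,-5,120,-,arthroscopic,130,0,130
4,F,68,130,-20,110,+,open,140,-10,130
5,M,48,130,-10,120,-,arthroscopic,140,0,140
6,M,56,110,-25,85,+,open,130,-10,120
7,M,72,115,-20,95,+,open,123,-22,101
8,M,60,110,0,110,+,open,118,0,118
9,M,69,130,-10,120,-,arthroscopic,134,-10,124
10,M,50,130,-10,120,-,arthroscopic,135,-5,130
11,M,51,110,-15,95,+,open,125,-10,115
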