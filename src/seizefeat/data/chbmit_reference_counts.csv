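mode,patient,trials,tp,fp,fn,tn
manual,1,42,7,0,0,49
manual,2,36,3,2,0,41
manual,3,38,7,2,0,47
manual,4,42,4,3,0,49
manual,5,39,5,3,0,47
manual,6,18,7,1,3,26
manual,7,19,3,3,0,14
manual,8,20,5,0,0,15
manual,9,19,4,0,0,23
manual,10,25,6,0,1,31
manual,11,35,3,2,0,40
manual,12,24,31,6,9,61
manual,13,33,8,8,4,48
manual,14,26,7,2,1,35
manual,15,36,18,6,1,64
manual,16,20,8,1,2,28
manual,17,23,3,0,0,24
manual,18,36,5,2,1,44
manual,19,30,3,0,0,33
manual,20,28,8,0,0,38
manual,21,33,4,1,0,38
manual,22,30,3,0,0,33
manual,23,9,6,0,1,16
manual,24,22,16,4,0,42
automated,1,42,6,3,1,48
automated,2,36,2,3,1,38
automated,3,38,7,0,0,45
automated,4,42,2,2,1,44
automated,5,39,5,1,0,44
automated,7,19,3,1,0,21
automated,8,20,5,0,0,25
automated,9,19,3,0,0,22
automated,10,25,6,1,1,31
automated,11,35,2,3,1,37
automated,17,23,3,0,0,26
automated,18,36,5,1,1,41
automated,19,30,3,0,0,33
automated,20,28,5,2,1,33
automated,22,30,3,1,0,33
automated,23,9,2,0,1,11
automated,24,22,15,2,1,36
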