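volunteer,range,frames,state,detection,variant
1,0~1.8,90,lying,lying,zmax
2,0~1.7,90,lying,lying,zmax
3,0~2.0,90,lying,lying,zmax
4,0~1.8,90,lying,lying,zmax
5,0~1.7,80,lying,lying,zmax
6,0~1.8,80,lying,lying,zmax
7,0~1.7,90,lying,lying,zmax
8,0~1.9,80,lying,lying,zmax
9,0~2.0,80,lying,lying,zmax
10,0~1.8,80,lying,lying,zmax
1,0~1.7,20,fall,fall,zmax
2,0~1.8,20,fall,fall,zmax
3,0~2.0,30,fall,fall,zmax
4,0~1.9,20,fall,fall,zmax
5,0~1.7,30,fall,lying,zmax
6,0~1.8,20,fall,fall,zmax
7,0~2.0,20,fall,fall,zmax
8,0~1.9,30,fall,fall,zmax
9,0~1.7,30,fall,fall,zmax
10,0~1.7,25,fall,fall,zmax
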