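volunteer,range,frames,state,detection,variant
1,−0.51~+0.65,90,lying,lying,velocity
2,−0.43~+0.65,90,lying,lying,velocity
3,−0.58~+0.72,90,lying,lying,velocity
4,−0.72~+0.80,90,lying,lying,velocity
5,−0.58~+0.80,80,lying,lying,velocity
6,−0.51~+0.80,80,lying,lying,velocity
7,−0.72~+0.80,90,lying,lying,velocity
8,−0.65~+0.72,80,lying,lying,velocity
9,−0.72~+0.72,80,lying,lying,velocity
10,−0.80~+0.65,80,lying,lying,velocity
1,−2.32~+2.10,20,fall,fall,velocity
2,−1.09~+1.88,20,fall,fall,velocity
3,−2.17~+2.25,30,fall,fall,velocity
4,−1.09~+2.25,20,fall,fall,velocity
5,−0.72~+1.88,30,fall,lying,velocity
6,−0.58~+2.17,20,fall,fall,velocity
7,−2.32~+1.74,20,fall,fall,velocity
8,−1.01~+1.74,30,fall,fall,velocity
9,−0.87~+2.25,30,fall,fall,velocity
10,−0.58~+1.59,25,fall,fall,velocity
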