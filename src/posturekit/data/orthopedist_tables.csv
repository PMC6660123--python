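user,direction,standard_g,measured_g
1,forward,0.99288,0.93354
1,left,-0.06689,0.00896
1,right,-0.06689,-0.17777
2,forward,0.98999,0.94897
2,left,-0.16921,-0.14087
2,right,-0.16921,-0.21952
3,forward,0.99846,0.98687
3,left,-0.06850,-0.01312
3,right,-0.06850,-0.12673
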