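picture_id,reported_2nd,generated_2nd,reported_3rd,generated_3rd,reported_total,generated_total
1,13.5,11.5,31,33.5,44.5,45
2,17,8.5,25.5,25,42.5,33.5
3,15,11.5,37,33.5,52,45
4,3,3.5,5,4.5,8,8
5,10.5,7.5,13.5,11,24,18.5
6,17.5,12.5,11,13.5,28.5,26
7,14.5,8.5,29.5,25,44,33.5
8,9.5,7.5,12.5,11,22,18.5
9,13.5,8.5,16,25,29.5,33.5
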