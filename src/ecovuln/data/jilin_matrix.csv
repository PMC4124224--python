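region,1,2,3,4,5,6,7,8,9,10
Tiaobei,0.461,0.246,0.59,90,67.5,20,22.5,5.96,0,75.27
Zhenlai,0.461,0.246,0.4,90.3,71.9,12.5,15.6,3.68,69.86,29.14
Tiaonan,0.432,0.099,1.71,87.1,80.6,9.7,22.6,4.91,62.13,23.46
Da'an,0.481,0.099,0,80.6,78.1,9.4,18.8,3.46,45.79,33.32
Tongyu,0.465,0.194,2.96,88.6,83.8,13.9,13.9,4.32,23.55,55.97
Qian'an,0.384,0.328,2.32,84.8,67.6,8.8,14.7,2.67,48.3,52.91
Fuyu,0.366,0.099,1.53,77.4,71.9,9.4,15.4,0,26.31,0
Changling,0.43,0.076,2.3,68.4,55.3,18.4,15.8,2.46,46.68,77.29
Qianguo,0.383,0.261,1.54,78.4,60.5,15.8,18.3,5.64,40.62,52.51
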