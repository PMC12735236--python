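compound,formula,rt,mz_measured,PIBOC O34-077,PIBOC O49-009,PIBOC O49-030,PIBOC O49-055,PIBOC O63-090,PIBOC O63-136,PIBOC O66-089,PIBOC O66-092,PIBOC O66-109
Rhabdastrelloside A,C44H73NO14,9.53,838.4961,3.6,51.4,87.1,53.5,14.1,100.0,2.1,8.7,3.5
Rhabdastrelloside B,C44H73NO13,10.54,822.5014,1.3,69.6,100.0,51.0,17.7,29.5,1.0,4.6,4.4
Stellettin W,C22H32O6,10.93,391.2135,60.5,89.1,26.8,17.8,100.0,61.2,23.0,24.0,37.0
Globostelletin N,C30H40O5,11.07,479.2805,41.7,28.9,14.7,20.9,37.7,12.6,99.3,91.0,100.0
Stellettin S,C19H28O3,11.41,303.1968,67.9,73.6,42.8,51.3,100.0,40.2,0,0,0.3
Globostelletin M,C30H40O5,12.11,479.2801,100.0,66.4,19.5,38.1,52.2,17.2,8.6,9.4,9.1
Globostelletin K,C30H40O5,12.28,479.2792,84.3,82.8,25.6,60.5,100.0,70.5,1.5,2.8,5.0
Jaspolide F,C25H34O4,13.09,397.2374,100.0,78.6,78.5,51.0,43.5,20.9,0.3,0.5,0.6
Globostelletin G,C25H34O4,13.50,397.2372,100.0,78.6,60.5,44.5,48.4,13.6,0,0,0
RAA,C30H40O4,16.87,463.2857,90.1,36.8,100.0,83.6,47.3,88.5,1.1,0.6,1.6
17Z-RAA,C30H40O4,17.27,463.2858,35.6,12.2,32.4,42.1,100.0,43.9,0.1,0.2,0.1
Stellettin E,C30H40O4,17.37,463.2852,78.2,17.2,66.3,74.5,100.0,68.4,0.4,0,0.1
Stellettin A,C30H38O4,17.54,461.2688,32.0,24.1,66.6,86.0,83.8,100.0,0.8,0,2.9
Stellettin B,C30H38O4,17.61,461.2698,14.4,8.7,30.7,93.0,83.1,100.0,0.5,0,2.2
Stellettin H,C32H44O5,20.03,507.3111,32.6,14.2,27.9,56.6,100.0,48.0,1.4,0.4,2.0
Stellettin I,C32H44O5,20.25,507.3112,100.0,11.5,19.5,56.1,99.7,58.8,0,0,0.7
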