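cultivar,yield_mean,yield_ebv,yield_rank,yala_mean,yala_ebv,yala_rank,maha_mean,maha_ebv,maha_rank,height_mean,height_ebv,height_rank
Bg407H,8.00,1.53,1,118.00,8.81,55,118.00,6.62,55,104.00,27.16,67
At307,7.00,1.03,2,97.00,-9.04,20,97.00,-11.23,20,59.00,-11.09,15
Bg369,7.00,1.03,2,104.00,-3.09,32,104.00,-5.28,32,59.00,-11.09,15
At362,7.00,1.03,2,110.00,2.01,51,110.00,-0.18,51,70.00,-1.74,37
Bw453,7.00,1.03,2,135.00,23.26,66,135.00,21.07,66,78.00,5.06,50
Bg305,6.90,0.98,6,94.00,-11.59,16,94.00,-13.78,16,70.00,-1.74,37
At402,6.70,0.88,7,115.00,6.26,53,115.00,4.07,53,85.00,11.01,57
Bg90-2,6.50,0.78,8,120.00,10.51,57,120.00,8.32,57,60.00,-10.24,18
Bg380,6.50,0.78,8,123.00,13.06,61,123.00,10.87,61,63.00,-7.69,22
At354,6.50,0.78,8,95.00,-10.74,17,95.00,-12.93,17,67.00,-4.29,30
At308,6.50,0.78,8,95.00,-10.74,17,95.00,-12.93,17,77.00,4.21,46
At303,6.20,0.63,12,90.00,-14.99,7,90.00,-17.18,7,74.00,1.66,44
Bg379-2,6.10,0.58,13,132.00,20.71,64,132.00,18.52,64,58.00,-11.94,13
Bg34-8,6.10,0.58,13,100.00,-6.49,23,100.00,-8.68,23,61.00,-9.39,20
At309,6.00,0.53,15,95.00,-10.74,17,95.00,-12.93,17,52.80,-16.36,6
Bg403,6.00,0.53,15,118.00,8.81,55,118.00,6.62,55,60.00,-10.24,18
Bg301,6.00,0.53,15,93.00,-12.44,12,93.00,-14.63,12,67.00,-4.29,30
Bg366,6.00,0.53,15,99.00,-7.34,22,99.00,-9.53,22,73.60,1.32,43
Bg455,6.00,0.53,15,130.00,19.01,63,130.00,16.82,63,77.00,4.21,46
Bg359,5.90,0.48,20,104.00,-3.09,32,104.00,-5.28,32,64.00,-6.84,24
Bg374,5.90,0.48,20,107.00,-0.54,49,107.00,-2.73,49,68.00,-3.44,35
Bg400-1,5.90,0.48,20,135.00,23.26,66,135.00,21.07,66,73.00,0.81,42
Bg357,5.80,0.43,23,104.00,-3.09,32,104.00,-5.28,32,56.00,-13.64,11
Bg310,5.60,0.33,24,97.00,-9.04,20,97.00,-11.23,20,65.00,-5.99,26
Bg251,5.50,0.28,25,80.00,-23.49,2,80.00,-25.68,2,87.00,12.71,60
Bg34-6,5.50,0.28,25,105.00,-2.24,37,105.00,-4.43,37,48.00,-20.44,3
Bw451,5.50,0.28,25,120.00,10.51,57,120.00,8.32,57,66.00,-5.14,27
Bg370,5.40,0.23,28,105.00,-2.24,37,105.00,-4.43,37,85.00,11.01,57
Bg450,5.30,0.18,29,125.00,14.76,62,125.00,12.57,62,64.00,-6.84,24
At353,5.20,0.13,30,90.00,-14.99,7,90.00,-17.18,7,80.00,6.76,51
At311,5.20,0.13,30,93.00,-12.44,12,93.00,-14.63,12,67.00,-4.29,30
Bw367,5.20,0.13,30,105.00,-2.24,37,105.00,-4.43,37,97.00,21.21,63
Bg250,4.50,-0.22,45,85.00,-19.24,3,85.00,-21.43,3,75.00,2.51,45
Bg252,4.20,-0.37,57,85.00,-19.24,3,85.00,-21.43,3,81.00,7.61,53
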