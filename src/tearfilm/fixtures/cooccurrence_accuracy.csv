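classifier,space,1,2,3,4,5,6,7,avg_printed
NB,grayscale,68.57,69.52,72.38,75.24,75.24,72.38,70.48,71.97
NB,lab,75.24,83.81,81.90,83.81,85.71,86.67,86.67,83.40
NB,opponent,67.62,73.33,72.38,73.33,74.29,74.29,75.24,72.93
LMT,grayscale,75.24,78.10,76.19,77.14,77.14,80.00,82.86,78.09
LMT,lab,80.00,82.86,80.00,83.81,86.67,86.67,82.86,83.27
LMT,opponent,70.48,80.95,78.10,81.90,76.19,79.05,80.95,78.23
RT,grayscale,74.29,63.81,75.24,74.29,78.10,71.43,71.43,72.66
RT,lab,68.57,76.19,76.19,80.95,71.43,71.43,76.19,74.42
RT,opponent,63.81,65.71,74.29,64.76,71.43,77.14,62.86,68.57
RF,grayscale,71.43,74.29,83.81,84.76,82.86,80.00,76.19,79.05
RF,lab,83.81,87.62,81.90,88.57,86.67,90.48,83.81,86.12
RF,opponent,77.14,81.90,73.33,82.86,78.10,82.86,82.86,79.86
SVM,grayscale,80.00,84.76,87.62,89.52,91.43,90.48,92.38,88.03
SVM,lab,89.52,90.48,94.29,94.29,95.24,96.19,95.24,93.60
SVM,opponent,85.71,89.52,90.48,89.52,90.48,90.48,91.43,89.66
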