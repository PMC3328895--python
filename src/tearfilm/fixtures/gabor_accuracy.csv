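classifier,space,3,5,7,9,avg_printed
NB,grayscale,60.00,59.05,58.10,60.00,59.29
NB,lab,81.90,82.86,82.86,82.86,82.62
NB,opponent,62.86,60.00,62.86,64.76,62.62
LMT,grayscale,80.95,77.14,74.29,75.24,76.91
LMT,lab,78.10,81.90,79.05,78.10,79.29
LMT,opponent,70.48,71.43,71.43,79.05,73.10
RT,grayscale,67.62,71.43,67.62,68.57,68.81
RT,lab,73.33,80.95,68.57,65.71,72.14
RT,opponent,64.76,65.71,66.67,61.90,64.76
RF,grayscale,73.33,66.67,72.38,69.52,70.48
RF,lab,78.10,76.19,81.90,75.24,77.86
RF,opponent,78.10,72.38,70.48,80.00,75.24
SVM,grayscale,88.57,87.62,86.67,86.67,87.38
SVM,lab,92.38,94.29,95.24,95.24,94.29
SVM,opponent,86.67,88.57,88.57,88.57,88.10
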