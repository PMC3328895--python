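classifier,space,1,2,3,4,5,6,7,8,9,avg_printed
NB,grayscale,50.48,59.05,65.71,60.00,59.05,55.24,48.57,46.67,43.81,54.29
NB,lab,65.71,71.43,79.05,77.14,74.29,70.48,66.67,46.67,44.76,66.24
NB,opponent,59.05,60.95,57.14,57.14,59.05,53.33,50.48,48.57,44.76,54.50
LMT,grayscale,62.86,53.33,58.10,62.86,64.76,66.67,58.10,54.29,43.81,58.31
LMT,lab,60.95,72.38,77.14,75.24,81.90,73.33,72.38,60.00,57.14,70.05
LMT,opponent,58.10,54.29,66.67,76.19,74.29,61.90,64.76,58.10,51.43,62.86
RT,grayscale,47.62,41.90,54.29,55.24,60.95,65.71,53.33,52.38,32.38,51.53
RT,lab,48.57,65.71,75.24,75.24,67.62,72.38,67.62,50.48,45.71,63.17
RT,opponent,48.57,53.33,61.90,67.62,53.33,60.00,62.86,58.10,55.24,57.88
RF,grayscale,42.86,48.57,62.86,60.00,66.67,64.76,60.00,50.48,48.57,58.09
RF,lab,63.81,76.19,79.05,80.00,75.24,78.10,74.29,61.90,56.19,71.64
RF,opponent,54.29,65.71,68.57,65.71,68.57,69.52,61.90,53.33,57.14,62.75
SVM,grayscale,61.90,57.14,73.33,72.38,72.38,66.67,68.57,61.90,53.33,62.59
SVM,lab,63.81,80.95,85.71,88.57,89.52,80.00,75.24,64.76,70.48,77.67
SVM,opponent,60.00,70.48,82.86,77.14,84.76,74.29,73.33,66.67,61.90,72.38
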