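classifier,space,1,2,3,4,5,6,7,8,9,10,avg_printed
NB,grayscale,38.10,37.14,38.10,36.19,36.19,36.19,35.24,35.24,34.29,33.33,36.00
NB,lab,45.71,42.86,39.05,31.43,31.43,30.48,32.38,31.43,30.48,30.48,34.57
NB,opponent,58.10,38.10,33.33,34.29,37.14,33.33,34.29,33.33,37.14,38.10,37.72
LMT,grayscale,51.43,65.71,60.00,55.24,59.05,53.33,60.95,53.33,52.38,64.76,57.62
LMT,lab,59.05,60.00,67.62,62.86,67.62,60.00,60.00,51.43,49.52,55.24,59.33
LMT,opponent,78.10,66.67,68.57,65.71,67.62,64.76,60.95,60.95,64.76,60.00,65.80
RT,grayscale,52.38,55.24,52.38,47.62,54.29,55.24,57.14,52.38,54.29,60.00,54.10
RT,lab,42.86,56.19,52.38,57.14,51.43,48.57,52.38,42.86,39.05,57.14,50.00
RT,opponent,67.62,58.10,57.14,52.38,59.05,52.38,49.52,50.48,50.48,58.10,55.23
RF,grayscale,57.14,71.43,63.81,59.05,58.10,60.95,60.00,60.95,60.00,68.57,62.00
RF,lab,51.43,59.05,66.67,55.24,60.00,55.24,60.95,61.90,55.24,62.86,58.89
RF,opponent,80.00,66.67,60.95,59.05,66.67,65.71,61.90,54.29,60.95,54.29,63.05
SVM,grayscale,61.90,78.10,78.10,83.81,81.90,80.00,75.24,76.19,73.33,77.14,76.57
SVM,lab,66.67,78.10,83.81,80.00,80.95,80.00,82.86,80.00,79.05,74.29,78.57
SVM,opponent,84.76,80.00,84.76,82.86,80.00,84.76,77.14,80.00,76.19,73.33,80.38
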