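classifier,space,accuracy
NB,grayscale,67.62
NB,lab,66.67
NB,opponent,62.86
LMT,grayscale,67.62
LMT,lab,80.95
LMT,opponent,76.19
RT,grayscale,73.33
RT,lab,71.43
RT,opponent,65.71
RF,grayscale,75.24
RF,lab,86.67
RF,opponent,70.48
SVM,grayscale,85.71
SVM,lab,88.57
SVM,opponent,84.76
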