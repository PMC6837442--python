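study,n,accuracy,year,modality,classifier
example-study-1,28,94.5,2012,brain imaging,SVM
example-study-2,164,71.2,2016,motion tracking,logistic regression
example-study-3,612,63.8,2018,other,random forest
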