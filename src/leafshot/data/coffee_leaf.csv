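class_id,disease,n_samples
CF1,Leaf miner,387
CF2,Rust,531
CF3,Brown leaf spot,348
CF4,Cercospora leaf spot,147
CF5,Several with same severity,62
CF6,Healthy,272
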