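class_id,disease,affected_plants,n_train,n_test
CD1,Apple scab,Apple,504,126
CD2,Bacterial spot,Peach;Pepper bell;Tomato,4337,1084
CD3,Black rot,Apple;Grape,1140,361
CD4,Cedar apple rust,Apple,220,55
CD5,Cercospora leaf spot Gray leaf spot,Corn,440,103
CD6,Common rust,Corn,953,239
CD7,Early blight,Potato;Tomato,1600,400
CD8,Esca black measles,Grape,1107,276
CD9,Haunglongbing Citrus greening,Orange,4405,1102
CD10,Late blight,Potato;Tomato,2327,582
CD11,Leaf blight Isariopsis Leaf Spot,Grape,861,215
CD12,Leaf mold,Tomato,761,191
CD13,Leaf scorch,Strawberry,887,222
CD14,Northern Leaf blight,Corn,817,197
CD15,Powdery mildew,Cherry;Squash,2310,577
CD16,Septoria leaf spot,Tomato,1417,354
CD17,Spider mites Two spotted spider mite,Tomato,1341,335
CD18,Target spot,Tomato,1123,281
CD19,Tomato mosaic virus,Tomato,299,74
CD20,Tomato Yellow Leaf Curl Virus,Tomato,4286,1071
CD21,Healthy,-,4909,1200
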