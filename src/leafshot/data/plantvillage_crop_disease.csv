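class_id,crop,disease,n_train,n_test
C1,Apple,Apple scab,504,126
C2,Apple,Black rot,496,125
C3,Apple,Cedar apple rust,220,55
C4,Apple,Healthy,1316,329
C5,Blueberry,Healthy,1202,300
C6,Cherry (including sour),Healthy,684,170
C7,Cherry (including sour),Powdery mildew,842,210
C8,Corn (maize),Cercospora leaf spot Gray leaf spot,410,103
C9,Corn (maize),Common rust,953,239
C10,Corn (maize),Healthy,929,233
C11,Corn (maize),Northern Leaf Blight,788,197
C12,Grape,Black rot,944,236
C13,Grape,Esca (Black Measles),1107,276
C14,Grape,Healthy,339,84
C15,Grape,Leaf blight (Isariopsis Leaf Spot),861,215
C16,Orange,Haunglongbing (Citrus greening),4405,1102
C17,Peach,Bacterial spot,1838,459
C18,Peach,Healthy,288,72
C19,Pepper bell,Bacterial spot,797,200
C20,Pepper bell,Healthy,1183,295
C21,Potato,Early blight,800,200
C22,Potato,Healthy,121,31
C23,Potato,Late blight,800,200
C24,Raspberry,Healthy,297,74
C25,Soybean,Healthy,4072,1018
C26,Squash,Powdery mildew,1468,367
C27,Strawberry,Healthy,364,92
C28,Strawberry,Leaf scorch,887,222
C29,Tomato,Bacterial spot,1702,425
C30,Tomato,Early blight,800,200
C31,Tomato,Healthy,1273,318
C32,Tomato,Late blight,1527,382
C33,Tomato,Leaf mold,761,191
C34,Tomato,Septoria leaf spot,1417,354
C35,Tomato,Spider mites Two-spotted spider mite,1341,335
C36,Tomato,Target spot,1123,281
C37,Tomato,Tomato mosaic virus,299,74
C38,Tomato,Tomato Yellow Leaf Curl Virus,4286,1071
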