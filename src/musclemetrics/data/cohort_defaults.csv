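muscle,mean_volume_cm3,sd_volume_cm3,mean_length_cm
Iliacus,113.8,17.3,20.0
Sartorius,83.0,29.6,44.0
Gluteus maximus,576.4,117.8,27.0
Gluteus medius,246.2,58.2,15.0
Tensor fasciae latae,41.6,12.8,15.0
Adductor brevis,58.9,10.6,13.0
Adductor longus,78.5,13.4,20.0
Adductor magnus,345.2,62.7,28.0
Gracilis,45.2,14.4,35.0
Biceps femoris long head,110.5,22.9,32.0
Biceps femoris short head,56.1,15.9,22.0
Semimembranosus,123.9,24.0,28.0
Semitendinosus,102.5,26.7,30.0
Rectus femoris,120.3,20.8,36.0
Vastus intermedius,266.9,38.5,33.0
Vastus lateralis,317.9,59.2,33.0
Vastus medialis,213.8,29.7,30.0
Tibialis anterior,94.7,15.3,28.0
Tibialis posterior,77.4,14.9,30.0
Gastrocnemius lateralis,75.4,15.2,22.0
Gastrocnemius medialis,160.6,29.3,25.0
Soleus,339.6,70.2,35.0
Peroneus brevis,34.8,8.0,22.0
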