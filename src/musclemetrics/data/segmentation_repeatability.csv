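muscle,segment,inter_op_cov_pct,intra_op_cov_pct
Iliacus,thigh_gluteal,8.0,2.6
Sartorius,thigh_gluteal,10.2,2.0
Gluteus maximus,thigh_gluteal,7.0,2.0
Gluteus medius,thigh_gluteal,10.6,5.3
Gluteus minimus,thigh_gluteal,14.6,21.6
Tensor fasciae latae,thigh_gluteal,12.4,1.1
Adductor brevis,thigh_gluteal,22.8,7.5
Adductor longus,thigh_gluteal,17.7,6.0
Adductor magnus,thigh_gluteal,5.9,3.6
Gracilis,thigh_gluteal,16.1,2.7
Biceps femoris long head,thigh_gluteal,7.6,4.7
Biceps femoris short head,thigh_gluteal,9.9,4.7
Semimembranosus,thigh_gluteal,9.7,6.9
Semitendinosus,thigh_gluteal,6.9,5.2
Rectus femoris,thigh_gluteal,7.0,5.6
Vastus intermedius,thigh_gluteal,6.6,1.1
Vastus lateralis,thigh_gluteal,9.8,1.2
Vastus medialis,thigh_gluteal,4.2,
Tibialis anterior,calf,25.3,4.2
Tibialis posterior,calf,12.1,8.9
Gastrocnemius lateralis,calf,4.6,
Gastrocnemius medialis,calf,4.5,
Soleus,calf,8.6,5.9
Peroneus brevis,calf,49.4,7.6
Peroneus longus,calf,48.2,10.9
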