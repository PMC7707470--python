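muscle,bundle,fmax_gen_n
Iliacus,Iliacus,1073
Sartorius,Sartorius,156
Gluteus maximus,Gluteus maximus I,573
Gluteus maximus,Gluteus maximus II,819
Gluteus maximus,Gluteus maximus III,552
Gluteus medius,Gluteus medius I,819
Gluteus medius,Gluteus medius II,573
Gluteus medius,Gluteus medius III,653
Gluteus minimus,Gluteus minimus I,270
Gluteus minimus,Gluteus minimus II,285
Gluteus minimus,Gluteus minimus III,323
Tensor fasciae latae,Tensor fasciae latae,233
Adductor brevis,Adductor brevis,429
Adductor longus,Adductor longus,627
Adductor magnus,Adductor magnus I,381
Adductor magnus,Adductor magnus II,343
Adductor magnus,Adductor magnus III,488
Gracilis,Gracilis,162
Biceps femoris long head,Biceps femoris long head,896
Biceps femoris short head,Biceps femoris short head,804
Semimembranosus,Semimembranosus,1288
Semitendinosus,Semitendinosus,410
Rectus femoris,Rectus femoris,779
Vastus intermedius,Vastus intermedius,1365
Vastus lateralis,Vastus lateralis,1871
Vastus medialis,Vastus medialis,1294
Tibialis anterior,Tibialis anterior,905
Tibialis posterior,Tibialis posterior,1270
Gastrocnemius lateralis,Gastrocnemius lateralis,488
Gastrocnemius medialis,Gastrocnemius medialis,1113
Soleus,Soleus,2839
Peroneus brevis,Peroneus brevis,348
Peroneus longus,Peroneus longus,754
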