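muscle,k,source
Iliacus,0.55,cadaveric literature
Sartorius,0.90,cadaveric literature
Gluteus maximus,0.58,cadaveric literature
Gluteus medius,0.37,cadaveric literature
Tensor fasciae latae,1.00,ratio unavailable; optimal fibre length set equal to muscle length
Adductor brevis,0.67,cadaveric literature
Adductor longus,0.50,cadaveric literature
Adductor magnus,0.38,cadaveric literature
Gracilis,0.79,cadaveric literature
Biceps femoris long head,0.28,cadaveric literature
Biceps femoris short head,0.49,cadaveric literature
Semimembranosus,0.26,cadaveric literature
Semitendinosus,0.62,cadaveric literature
Rectus femoris,0.19,cadaveric literature
Vastus intermedius,0.24,cadaveric literature
Vastus lateralis,0.36,cadaveric literature
Vastus medialis,0.22,cadaveric literature
Tibialis anterior,0.27,cadaveric literature
Tibialis posterior,0.08,cadaveric literature
Gastrocnemius lateralis,0.26,cadaveric literature
Gastrocnemius medialis,0.20,cadaveric literature
Soleus,0.10,cadaveric literature
Peroneus brevis,0.19,cadaveric literature
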