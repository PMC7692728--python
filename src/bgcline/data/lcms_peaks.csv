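peak,rt_min,mz,strain,media
1,2.2,597.29,rumicis,TSA2
2,2.5,554.28,rumicis,TSA2
3,2.8,656.31,flavus,TSA2
3,2.8,656.31,houttuyneae,TSA2
3,2.8,656.31,suffuscus,TSA2
4,6.3,505.40,suffuscus,TSA2;ISP2_2
5,7.2,812.44,houttuyneae,TSA2;ISP2_2
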