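>P5_At1 organism=Arabidopsis_thaliana synthetic=true
CRTISDHYHFFTGALRRNHAPPALPKYWLKLACEVWDSSGRVSRDFPQTKVCADLIKCRMDMNWKFDKTGTYHAAYMQVEPPEAADYCHSA
>P5_At2 organism=Arabidopsis_thaliana synthetic=true
CDTHSPPYHFFTGQLRRNQAPPALPKYWLKLACEPNDISGSSSRDFPQTYVCADLICCRMDMNWKPDKTGTYHAACMDSEPPEAARYCHSA
>P5_Os1 organism=Oryza_sativa synthetic=true
CDTISPPMHFFTGQLRVKQAPPALPKYWLKGACHPWDISGSSSRDFPQTKVCADLICCRMDPNWKPDKTGTYHFAYMDSEPPEAARYCISF
>P5_Os2 organism=Oryza_sativa synthetic=true
CGTISPPYHFFTWQLRRNQAPPALPKYWLKLAYEPWDISGSSSRDFPQAKVCADDILCRMDMNAKPDKTGTYHAAYMDSHPPEAARYCHSA
>P5_Hv1 organism=Hordeum_vulgare synthetic=true
CDTISMPAHFFTGTMRSNQAPPSLPKYWLKLISESWDQSGSSSRDFPQTKKCADLIDCRMDHNWVPDKTGTYHAAYMDSEPPEAAFYCHSA
>P5_Hv2 organism=Hordeum_vulgare synthetic=true
CDLISCPYHFFTGQDRRNQAPPSLPKYWSKLACEPWDISGSMSRDFPVTKVCADLICCRMDMNWKLDKTGTYAAAYMDSEPPEAARYCHSA
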