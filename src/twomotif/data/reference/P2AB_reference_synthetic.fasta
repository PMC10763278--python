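>P2AB_At1 organism=Arabidopsis_thaliana synthetic=true
LDRPENCYVWCTCYSNESCHPEGLHWQTDNVGYLPERKEPPFYEWLHMQDEKPAPKFATDVVDKTGTFMGDLVETLEISKPPHVWIC
>P2AB_At2 organism=Arabidopsis_thaliana synthetic=true
RDKPEYCGVWCVCNNNESCHPEGLHWQTDFVGYLPERKEPPHYRWLHMQDEKFAQKFAHDVVDKTGTFMGMLVENLEISKPPHVWIC
>P2AB_Os1 organism=Oryza_sativa synthetic=true
RDRPENCGVWCLWNSNESCHPESLHWQTDNGGYLPERKECPFYEWLHCQDEKPAIAFAHMVVDKTGTFMGMLVENLEISKHPHVWIC
>P2AB_Os2 organism=Oryza_sativa synthetic=true
RDRPENCGVWCKCNSNQSCHPESLDWQHDNVGYLPERKEPKFYEGLHMQDEKPAPKFAHDVADKTGTGVGMLVENLEISKPPHVDYP
>P2AB_Hv1 organism=Hordeum_vulgare synthetic=true
RDRPENCGVWVLCNSNVSCHPEGLHWQNDNVGYLPERKCPYFYEDLHYQDEKPAPKFAHDVVDKTGTFMGMLVENLVISKPPHKWIC
>P2AB_Hv2 organism=Hordeum_vulgare synthetic=true
RDEPRNCGVWCLCNSNESCHPEGLHTQTDNVGYFPERKMWPFYEWLHMQDEKPAPKVAHDVVDKTGTFMGMLVENLEISKPPHVWIT
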