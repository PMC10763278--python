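>P1B_At1 organism=Arabidopsis_thaliana synthetic=true
FYCFHHWSWYCFVCEEWIGECPCLNTPYRLNQCGACYHSMNHHDFSKTGRITFIGSTKDKTGTGHGECSLYGQVPGISILLLL
>P1B_At2 organism=Arabidopsis_thaliana synthetic=true
FQCFHHWSWYCDVCWCWIGECPCLNFPYDLNQWFLCYPSMNHHDFPKTGAVTFIGITKDKTGTGCGECLLSGIVSGISILLLL
>P1B_Os1 organism=Oryza_sativa synthetic=true
FQCFHHWSWGCDVCELWIGECPCLNTPYDLNQAFLCYPSMNHHDFSKTGRNTFIGSTKDKTGTGCGECSLYGIVPGISILLLS
>P1B_Os2 organism=Oryza_sativa synthetic=true
FQCFTHWSWYKDVCEEWIGECPCDNTPYDLNQAFLWYPSMNHHDMSKTGDVTFIGSTKDKTGTNCGECSLYGIEPGISILLLL
>P1B_Hv1 organism=Hordeum_vulgare synthetic=true
FQCFHHWLWYCDVCECWYGESPCLNTFYDLNPAFLCIPSMNLHNFSKTGRVTFIGSAKDKTGTGCGECSLYGFVPTISILLLL
>P1B_Hv2 organism=Hordeum_vulgare synthetic=true
FQCFHKWSWYCDVCEEWIGESPCLNRPYDLNQAFHCYVSMNHHDFSKTGRVTFIGSTKDKTGTLCGECSLYGIVPGISILLLL
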