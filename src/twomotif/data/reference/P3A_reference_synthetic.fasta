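>P3A_At1 organism=Arabidopsis_thaliana synthetic=true
EFPIFTLFLMGPWQMDQLTAPIAKYYSPMGVPKRQTALMRISDIQWDKTIAVYNLQNPDWHMIDKTGTLRFNDDEGEKNAQMYHWITQ
>P3A_At2 organism=Arabidopsis_thaliana synthetic=true
AETIRTVFLMGPLQMDQKTKPIAKYYLPMGVPKRQTAEMRISDIQWDKNIAVYNLQNPDWQMIDKTGTLRHNDDSGEKLAQMYHWIDA
>P3A_Os1 organism=Oryza_sativa synthetic=true
EFPIRTKFLMGPLQMDQGTAPIAKYYKPACVPKRNTALMRISDIQWDKTIAVYNLQNPDWQMIDKTGTLWHVDDSGEKLAQMYHWIDA
>P3A_Os2 organism=Oryza_sativa synthetic=true
EFPIRTKFLMMPLGMDLGTAPIAKYYSPMGVHKRQTALMRLSDIQWDKTILVYNLQNPDWQMIDKTGTLRFNDDSGEKFAQMYHWIDA
>P3A_Hv1 organism=Hordeum_vulgare synthetic=true
EFPIRTKFAMGPLQMDQGTAPIAKYYSPMGVPKRQTALKRISDIQWDKTIAVYNLQNPDWQMIDKTGTLGFNRDSGEKLAQMYHWIMA
>P3A_Hv2 organism=Hordeum_vulgare synthetic=true
EFPIRTMTIMGVLQMDQGTAPIAKYYMKMEVPKRQTAMMRISDIQWDKTIAVYNLQINDWQMIDKTGTLRFNDDSGGKLAQCYHWIDA
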