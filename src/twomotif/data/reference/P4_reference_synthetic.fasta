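>P4_At1 organism=Arabidopsis_thaliana synthetic=true
DPQISQMHNPHMDRWHIQGPPISWSHQPINDTTYVIEKHVRTWFGCHAICHGSEQSKDIGRNCYRIDKTGTGIIPAHWNTTKNITDYNAGH
>P4_At2 organism=Arabidopsis_thaliana synthetic=true
DKQISQMHNPHHDRWCIQGPPISWSHQPLNDEKYVIMLHVRTWFGCHAKMHGSGQSKDIWRPCGRIDKTGTGIIPAHHNTTKNITDYNDKH
>P4_Os1 organism=Oryza_sativa synthetic=true
DPQISQMHNTHHDRWCIQFPPISWSHQPLNDEKYVIMLHVHTWFGCHAKMMGSGQSKDIGRNCYRIDKTGTGIIPYHWNTTKNITDYNDGH
>P4_Os2 organism=Oryza_sativa synthetic=true
YPQIQQMHNPHHDRWCIQDSPISRSHQPNNDEAYVIMTHVRTWFGCHAKMHKSGPSMSIDRNCYRIDKTGTGIIPAHWNTYKNITDYNDGH
>P4_Hv1 organism=Hordeum_vulgare synthetic=true
DPQISQMHNPHHDRWCIQGPPISGSHQPLNDEKYVIQLHVRKWF-CHAKMHGSGQSKDIGRNCYRIDKTGTGIIPAHWKTTKNITDYNDGH
>P4_Hv2 organism=Hordeum_vulgare synthetic=true
DPQISQMHNQHHDRWCIQGPPISWSGQPLNDEKYVILLHVRTWF-CHAKMHGSGQSKDIGRNCYRRDKTGTGSIPAHINTTKSITDYNDYH
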