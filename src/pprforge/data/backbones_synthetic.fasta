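>dsnSa synthetic stand-in consensus backbone (31 aa)
VTYNTLIGGLCKAGKLDEALELFNEMREKGV
>dsnSb synthetic stand-in consensus backbone (31 aa)
VTYTTLIHGLCKVGKVDEAIALLDEMVSKGI
>dsnSc synthetic stand-in consensus backbone (31 aa)
VTYNALINGLCKEGKVDEAFELFDEMKGKGL
>dsnSd synthetic stand-in consensus backbone (31 aa)
VSYSTLIDGLCKNGKLDEALALFREMEEKGL
>P2 synthetic stand-in consensus backbone (35 aa)
GVVPNVVTYNTLIDGLCKAGKLDEAEELFEEMQKR
>L2 synthetic stand-in consensus backbone (36 aa)
GLKPDVITYNSLINGYCKAGRLDEAKKLLNEMSSKG
>S2 synthetic stand-in consensus backbone (32 aa)
LIPDVVTYSTLIDGLCKAGKTDEALKLFREMQ
>E1 synthetic stand-in consensus backbone (34 aa)
GCSPNVVTYTALIDGLCKSGKVEEACELFDEMIQ
>E2 synthetic stand-in consensus backbone (34 aa)
RGISPNVITYNTLIDGLCKAGKFDEAMALFEEMK
>DYW synthetic stand-in consensus backbone (69 aa)
HSEKLAIAFGLISTPPGTPLRIFKNLRVCGDCHNAIKYISKIVGVTIIVRDNLRFHHFKDGSCSCGDYW
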