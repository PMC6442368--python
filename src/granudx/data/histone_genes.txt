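# Default histone gene symbols used to anchor the proteomic ruler.
# Covers the H1, H2A, H2B, H3 and H4 families under both the current
# HGNC nomenclature (H2AC.., H2BC.., H3C.., H4C.., H1-..) and the legacy
# HIST1/HIST2/HIST3 cluster names, plus the replication-independent
# variants. Override with your own list if your annotation differs.
H1-0
H1-1
H1-2
H1-3
H1-4
H1-5
H1-6
H1-10
H2AC1
H2AC4
H2AC6
H2AC11
H2AC12
H2AC13
H2AC14
H2AC15
H2AC16
H2AC17
H2AC18
H2AC19
H2AC20
H2AC21
H2AZ1
H2AZ2
H2AX
H2AJ
MACROH2A1
MACROH2A2
H2BC1
H2BC3
H2BC4
H2BC5
H2BC6
H2BC7
H2BC8
H2BC9
H2BC10
H2BC11
H2BC12
H2BC13
H2BC14
H2BC15
H2BC17
H2BC18
H2BC21
H3C1
H3C2
H3C3
H3C4
H3C6
H3C7
H3C8
H3C10
H3C11
H3C12
H3C13
H3C14
H3C15
H3-3A
H3-3B
H3-4
H3-5
CENPA
H4C1
H4C2
H4C3
H4C4
H4C5
H4C6
H4C8
H4C9
H4C11
H4C12
H4C13
H4C14
H4C15
H4-16
HIST1H1A
HIST1H1B
HIST1H1C
HIST1H1D
HIST1H1E
HIST1H1T
HIST1H2AB
HIST1H2AC
HIST1H2AD
HIST1H2AE
HIST1H2AG
HIST1H2AH
HIST1H2AI
HIST1H2AJ
HIST1H2AK
HIST1H2AL
HIST1H2AM
HIST1H2BA
HIST1H2BB
HIST1H2BC
HIST1H2BD
HIST1H2BE
HIST1H2BF
HIST1H2BG
HIST1H2BH
HIST1H2BI
HIST1H2BJ
HIST1H2BK
HIST1H2BL
HIST1H2BM
HIST1H2BN
HIST1H2BO
HIST1H3A
HIST1H3B
HIST1H3C
HIST1H3D
HIST1H3E
HIST1H3F
HIST1H3G
HIST1H3H
HIST1H3I
HIST1H3J
HIST1H4A
HIST1H4B
HIST1H4C
HIST1H4D
HIST1H4E
HIST1H4F
HIST1H4H
HIST1H4I
HIST1H4J
HIST1H4K
HIST1H4L
HIST2H2AA3
HIST2H2AA4
HIST2H2AB
HIST2H2AC
HIST2H2BE
HIST2H2BF
HIST2H3A
HIST2H3C
HIST2H3D
HIST2H4A
HIST2H4B
HIST3H2A
HIST3H2BB
HIST3H3
HIST4H4
H2AFZ
H2AFX
H2AFJ
H2AFV
H2AFY
H2AFY2
H3F3A
H3F3B
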