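"""The published 1974 amino-acid substitution distance table, used as an
independent oracle against the formula-based implementation.

One entry needs a note: Asp-Trp is 191 by the defining formula; some widely
circulated copies of the table print 181, a digit transposition inconsistent
with the formula and with every other entry. The formula value is used here.
"""

_RAW = """
RS110 LS145 LR102 PS74 PR103 PL98 TS58 TR71 TL92 TP38 AS99 AR112 AL96 AP27 AT58
VS124 VR96 VL32 VP68 VT69 VA64 GS56 GR125 GL138 GP42 GT59 GA60 GV109
IS142 IR97 IL5 IP95 IT89 IA94 IV29 IG135
FS155 FR97 FL22 FP114 FT103 FA113 FV50 FG153 FI21
YS144 YR77 YL36 YP110 YT92 YA112 YV55 YG147 YI33 YF22
CS112 CR180 CL198 CP169 CT149 CA195 CV192 CG159 CI198 CF205 CY194
HS89 HR29 HL99 HP77 HT47 HA86 HV84 HG98 HI94 HF100 HY83 HC174
QS68 QR43 QL113 QP76 QT42 QA91 QV96 QG87 QI109 QF116 QY99 QC154 QH24
NS46 NR86 NL153 NP91 NT65 NA111 NV133 NG80 NI149 NF158 NY143 NC139 NH68 NQ46
KS121 KR26 KL107 KP103 KT78 KA106 KV97 KG127 KI102 KF102 KY85 KC202 KH32 KQ53 KN94
DS65 DR96 DL172 DP108 DT85 DA126 DV152 DG94 DI168 DF177 DY160 DC154 DH81 DQ61 DN23 DK101
ES80 ER54 EL138 EP93 ET65 EA107 EV121 EG98 EI134 EF140 EY122 EC170 EH40 EQ29 EN42 EK56 ED45
MS135 MR91 ML15 MP87 MT81 MA84 MV21 MG127 MI10 MF28 MY36 MC196 MH87 MQ101 MN142 MK95 MD160 ME126
WS177 WR101 WL61 WP147 WT128 WA148 WV88 WG184 WI61 WF40 WY37 WC215 WH115 WQ130 WN174 WK110 WD191 WE152 WM67
"""

PUBLISHED_DISTANCES = {}
for _tok in _RAW.split():
    PUBLISHED_DISTANCES[frozenset((_tok[0], _tok[1]))] = int(_tok[2:])

assert len(PUBLISHED_DISTANCES) == 190
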