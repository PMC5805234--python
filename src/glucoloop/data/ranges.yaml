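# Physiological bands (closed intervals [LL, HL]) per model variable.
# Whole-body bands are editable literature-standard placeholders spanning
# the fasting-to-postprandial envelope; cellular bands are inferred in
# silico from the cascade's conserved totals (0 to just above the NGR
# pool size).  Variables marked "unbounded" are excluded from range
# validation.
S:     {LL: 0.0, HL: 200000.0}   # stomach glucose (mg)
L:     {LL: 0.0, HL: 200000.0}   # intestine glucose (mg)
G:     {LL: 60.0, HL: 200.0}     # plasma glucose (mg/dL)
I:     {LL: 2.0, HL: 80.0}       # plasma insulin (uU/mL)
W:     {LL: 5.0, HL: 150.0}      # incretin (pmol/L)
E:     {LL: 20.0, HL: 200.0}     # glucagon (pg/mL)
C:     {LL: 0.0, HL: 50000.0}    # liver glucose mass (mg)
M:     {LL: 0.0, HL: 50000.0}    # muscle glucose mass (mg)
A:     {LL: 0.0, HL: 50000.0}    # adipose glucose mass (mg)
Y:     {LL: 2.0, HL: 40.0}       # leptin (ng/mL)
Q:     {LL: 100.0, HL: 2000.0}   # ghrelin (pg/mL)
H:     {LL: 0.0, HL: 200000.0}   # hunger signal (mg)
INS_A: {LL: 0.0, HL: 200.0}      # interstitial insulin deviation (uU/mL)
Gt_A:  {LL: 0.0, HL: 200.0}      # interstitial glucose deviation (mg/dL)
# cellular species (a.u.): bounded by the conserved pool with 1% headroom
IR:              {LL: 0.0, HL: 101.0}
IR_YP:           {LL: 0.0, HL: 101.0}
IRins:           {LL: 0.0, HL: 101.0}
IRi_YP:          {LL: 0.0, HL: 101.0}
IRi:             {LL: 0.0, HL: 101.0}
IRS1:            {LL: 0.0, HL: 101.0}
IRS1_YP:         {LL: 0.0, HL: 101.0}
IRS1_YP_S307P:   {LL: 0.0, HL: 101.0}
IRS1_S307P:      {LL: 0.0, HL: 101.0}
X:               {LL: 0.0, HL: 101.0}
X_P:             {LL: 0.0, HL: 101.0}
PKB:             {LL: 0.0, HL: 101.0}
PKB_T308P:       {LL: 0.0, HL: 101.0}
PKB_S473P:       {LL: 0.0, HL: 101.0}
PKB_T308P_S473P: {LL: 0.0, HL: 101.0}
mTORC1:          {LL: 0.0, HL: 101.0}
mTORC1a:         {LL: 0.0, HL: 101.0}
mTORC2:          {LL: 0.0, HL: 101.0}
mTORC2a:         {LL: 0.0, HL: 101.0}
AS160:           {LL: 0.0, HL: 101.0}
AS160_T642P:     {LL: 0.0, HL: 101.0}
GLUT4:           {LL: 0.0, HL: 101.0}
GLUT4m:          {LL: 0.0, HL: 101.0}
S6K:             {LL: 0.0, HL: 101.0}
S6K_T389P:       {LL: 0.0, HL: 101.0}
S6:              {LL: 0.0, HL: 101.0}
S6_S235_S236P:   {LL: 0.0, HL: 101.0}
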