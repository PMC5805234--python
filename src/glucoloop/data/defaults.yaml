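# Default parameter and fasting initial-value tables for the closed-loop
# glucose homeostasis model.
#
# Whole-body rates are anchored to literature-standard fasting physiology
# (basal glucose/insulin turnover, gastric emptying and hormone half-lives)
# and then calibrated by the package's parameter workflow so that the
# closed loop self-sustains recurrent meals inside the physiological bands
# of ranges.yaml.  The eight steady-state-derived parameters (b4, b5, b12,
# b13, b17, b27, c, c3) are intentionally absent: they are recomputed from
# these tables at preset-build time.
#
# Cellular rate constants are this package's own mass-action
# parameterization in arbitrary units (protein totals of 100 a.u.,
# minute-scale kinetics); see docs/methods.md.
#
# T2DM entries override the NGR base section by section, so the alternate
# condition is expressed as a diff: reduced insulin effectiveness e,
# increased fat mass, raised basal glucose/insulin, reduced receptor and
# GLUT4 totals and reduced mTORC1 feedback kfb.

steady_state:
  rho: 0.5          # incretin fraction of basal insulin secretion

conditions:
  NGR:
    whole_body:
      b1: 4.0e-4    # insulin-independent glucose elimination (1/min)
      b2: 0.06      # insulin elimination (1/min)
      b3: 1.2e-3    # insulin-dependent glucose elimination (mL/uU/min)
      b6: 5.2e-5    # incretin secretion per mg intestinal glucose
      b7: 0.06      # incretin elimination (1/min)
      b8: 0.018      # stomach emptying (1/min)
      b9: 0.02      # hunger-to-stomach intake (1/min)
      b10: 0.02     # intestine-to-plasma transfer (1/min)
      b11: 0.0032    # ghrelin elimination (1/min)
      b14: 0.002    # leptin elimination (1/min)
      b18: 0.1      # leptin inhibition scale on hunger (mL/ng)
      b19: 4.0e-6   # glucose-dependent hunger decay (dL/mg/min)
      b21: 0.12      # glucagon-dependent liver glucose production
      b22: 0.28      # glucose inhibition of liver production
      b23: 120.0    # basal liver glucose production (mg/min)
      b25: 0.2      # insulin inhibition of liver production
      c0: 1.4       # basal glucagon secretion (pg/mL/min)
      c1: 40.0     # gated glucagon secretion scale
      c2: 1.0       # insulin offset in glucagon suppression
      e: 1.0        # insulin effectiveness (maximal in NGR)
      Ge: 80.0      # glucagon glucose threshold (mg/dL)
      f: 0.9        # absorbed fraction
      v: 120.0      # glucose distribution volume (dL)
      l: 1.0e-4     # stomach-glucose decay of ghrelin secretion (1/mg)
      m: 0.05       # insulin decay of ghrelin secretion (mL/uU)
      r: 1.5       # insulin inhibition of hunger (mL/uU)
      s: 1.2        # constant incretin appearance (pmol/L/min)
      Fat: 20.0     # total fat mass (kg)
      Ib: 10.0      # basal plasma insulin (uU/mL)
      Gb: 90.0      # basal plasma glucose (mg/dL)
      p2U: 0.02     # interstitial insulin transfer/degradation (1/min)
      q1: 0.02      # interstitial glucose degradation (1/min)
      q2: 0.02      # plasma-to-interstitium glucose transfer (1/min)
    cellular:
      k1a: 0.05
      k1basal: 0.01
      k1c: 1.0
      k1d: 0.5
      k1f: 0.02
      k1g: 0.5
      k1r: 0.2
      k2a: 0.02
      k2b: 1.0
      k2c: 0.3
      k2d: 0.5
      k2f: 0.2
      k2g: 0.5
      k2basal: 0.01
      kfb: 0.1
      k3a: 0.002
      k3b: 0.02
      k4a: 0.01
      k4b: 0.5
      k4c: 0.02
      k4e: 0.005
      k4f: 0.5
      k4h: 0.2
      k5a1: 0.02
      k5a2: 0.005
      k5b: 0.5
      k5c: 0.02
      k5d: 0.5
      k6a1: 0.02
      k6a2: 0.005
      k6b: 0.5
      k7a: 0.01
      k7b: 0.2
      k9a: 0.005
      k9b: 0.1
      k9f2: 0.005
      k9b2: 0.1
      GLUT1: 8.0    # constitutive transporter flux scale (mg/min at saturation)
      k8: 0.25      # GLUT4m flux scale (mg/min per a.u.)
      KmG4: 50.0    # half-saturation of GLUT4 route (mg/dL)
      KmG1: 50.0    # half-saturation of GLUT1 route (mg/dL)
      kgluc: 8.0e-4  # adipose glucose elimination (1/min)
    initial_whole_body:
      S: 0.0        # empty stomach at morning fast (mg)
      L: 0.0        # empty intestine (mg)
      G: 90.0       # fasting plasma glucose (mg/dL)
      I: 10.0       # fasting plasma insulin (uU/mL)
      W: 20.0       # basal incretin (pmol/L)
      E: 70.0       # fasting glucagon (pg/mL)
      C: 4000.0     # liver glucose ready for secretion (mg)
      M: 2000.0     # muscle glucose mass (mg)
      A: 3000.0     # adipose glucose mass (mg)
      Y: 10.0       # fasting leptin (ng/mL)
      Q: 800.0      # fasting ghrelin (pg/mL)
      H: 30000.0    # glucose needed at fast (mg)
      INS_A: 0.0
      Gt_A: 0.0
    initial_cellular:
      # seed masses per protein pool; the preset builder relaxes these to
      # the unstimulated (INS_A = 0) steady state before simulating
      IR: 100.0
      IRS1: 100.0
      X: 100.0
      PKB: 100.0
      mTORC1: 100.0
      mTORC2: 100.0
      AS160: 100.0
      GLUT4: 100.0
      S6K: 100.0
      S6: 100.0

  T2DM:
    whole_body:
      e: 0.5        # reduced insulin effectiveness
      Fat: 30.0     # increased fat mass (kg)
      Ib: 15.0      # raised basal insulin (uU/mL)
      Gb: 140.0     # raised basal glucose (mg/dL)
      b3: 2.0e-3    # insulin-dependent plasma disposal, condition estimate
      b23: 450.0    # pathologically elevated hepatic glucose production
      r: 2.5        # insulin inhibition of hunger, condition estimate
    cellular:
      kfb: 0.02     # reduced mTORC1 positive feedback
    initial_whole_body:
      G: 140.0      # fasting hyperglycemia
      I: 15.0       # fasting hyperinsulinemia
      E: 80.0
      C: 3500.0
      M: 1800.0
      A: 1700.0     # reduced adipose glucose mass
      Y: 15.0       # raised leptin with increased fat mass
      Q: 600.0      # blunted fasting ghrelin
      H: 70000.0
    initial_cellular:
      IR: 55.0      # reduced receptor total
      GLUT4: 50.0   # reduced GLUT4 total
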