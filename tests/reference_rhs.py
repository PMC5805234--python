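"""Independent term-by-term transcription of the whole-body rate equations.

Written directly from the printed equation forms, deliberately sharing no
code with the package implementation; serves as the cross-check oracle for
the whole-body right-hand side.
"""

import math


def reference_whole_body_rhs(s: dict, uptake_flux: float, p) -> dict:
    """State dict -> derivative dict, one printed equation per line."""
    u = 1.0 if (p.Ge - s["G"]) >= 0 else 0.0
    return {
        "S": p.b9 * s["H"] - p.b8 * s["S"],
        "L": p.b8 * s["S"] - p.b10 * s["L"],
        "G": (p.f * p.b10 * s["L"] / p.v + p.f * p.b5 * s["C"] / p.v
              - p.b1 * s["G"] - p.b3 * s["I"] * s["G"]),
        "I": p.b4 * s["G"] + p.c * s["W"] * s["G"] - p.b2 * s["I"],
        "W": p.b6 * s["L"] - p.b7 * s["W"] + p.s,
        "E": (p.c0 + p.c1 / (p.c2 + s["I"] * p.e) * (p.Ge - s["G"]) * u
              - p.c3 * s["E"]),
        "C": (p.b23 - p.b25 * s["I"] * p.e - p.b22 * s["G"]
              + p.b21 * s["E"] - p.b5 * s["C"]),
        "M": 0.1 * p.v * p.f * p.b3 * s["G"] * s["I"] * p.e - p.b27 * s["M"],
        "A": uptake_flux - p.kgluc * s["A"],
        "Y": p.b13 * s["A"] / p.Fat - p.b14 * s["Y"],
        "Q": (p.b12 * math.exp(-p.l * s["S"]) * math.exp(-p.m * s["I"])
              - p.b11 * s["Q"]),
        "H": (p.b17 * s["Q"] / (p.b18 * s["Y"] + 1.0) * math.exp(-p.r * s["I"])
              - p.b19 * s["G"] * s["H"] - p.b9 * s["H"]),
        "INS_A": -p.p2U * s["INS_A"] + p.p2U * max(s["I"] - p.Ib, 0.0),
        "Gt_A": -p.q1 * s["Gt_A"] + p.q2 * max(s["G"] - p.Gb, 0.0),
    }
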