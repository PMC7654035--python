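#!/usr/bin/env python
"""Kinetic calibration report: evaluates the default growth model at its
anchor conditions and prints targets vs realized values, plus the emergent
substrate consumption rates per regime.

    python scripts/calibrate_kinetics.py
"""

from __future__ import annotations

from magnetoferm.bioreactor import KineticParams, growth_rate


def main() -> None:
    p = KineticParams()
    sat = 1e9
    anchors = [
        ("mu @ 95% dO2, saturating substrates", growth_rate(p, 95.0, sat, sat), p.mu_max_ox),
        ("mu @ 1% dO2, saturating substrates", growth_rate(p, 1.0, sat, sat), p.mu_max_micro),
        ("mu @ 0% dO2, 10 mM nitrate", growth_rate(p, 0.0, sat, 10.0), p.mu_max_anox),
        ("mu @ 1% dO2, medium (15 mM lac, 4 mM NO3)", growth_rate(p, 1.0, 15.0, 4.0), p.mu_max_micro),
    ]
    print("derived constants:")
    print(f"  mu_max         = {p.mu_max:.6f} 1/h")
    print(f"  stress slope   = {p.stress_slope:.6f} per % dO2")
    print(f"  denit. eff.    = {p.denit_eff:.6f}")
    print(f"  Y_lac (OD/mM)  = {p.y_lac_od:.6f}")
    print("\ngrowth-rate anchors (realized vs target, tolerance 5%):")
    for label, got, want in anchors:
        flag = "ok" if abs(got - want) <= 0.05 * want else "OFF"
        print(f"  {label:45s} {got:.4f} vs {want:.4f}  [{flag}]")

    print("\nemergent nitrate consumption (mM/h per OD):")
    for c, label in ((95.0, "oxic"), (1.0, "microoxic"), (0.0, "anoxic")):
        fnr = p.K_fnr / (p.K_fnr + c)
        for no3 in (4.0, 10.0):
            q = (p.q_no3_assim + p.q_no3_resp * fnr) * no3 / (p.K_no3 + no3)
            print(f"  {label:10s} dO2={c:5.1f}% NO3={no3:4.1f} mM -> {q:.3f}")

    print("\nemergent lactate consumption mu/Y (mM/h per OD):")
    for c, no3, label in ((95.0, 4.0, "oxic"), (1.0, 4.0, "microoxic"), (0.0, 10.0, "anoxic")):
        mu = growth_rate(p, c, 15.0, no3)
        print(f"  {label:10s} -> {mu / p.y_lac_od:.3f}")


if __name__ == "__main__":
    main()
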