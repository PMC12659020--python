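"""Two-point complete-basis-set extrapolation arithmetic.

E(X) = E_CBS + A·X^(−β) for basis cardinal number X; two basis sets
eliminate A.  The utility is unit-agnostic — feed it hartree or eV.
"""

from deltamd import cbs_extrapolate

# synthetic correlation energies following the inverse-cube law exactly
E_inf, A = -76.36, 1.85
E_TZ = E_inf + A * 3 ** -3   # triple zeta
E_QZ = E_inf + A * 4 ** -3   # quadruple zeta
est = cbs_extrapolate(E_TZ, E_QZ, X=3, Y=4, beta=3)
print(f"E(TZ) = {E_TZ:.6f},  E(QZ) = {E_QZ:.6f}")
print(f"CBS(TZ/QZ) = {est:.6f}   (planted limit {E_inf:.6f}, recovered exactly)")

# worked example with round numbers
print(f"\nCBS(TZ/QZ) of (−1.000, −1.037): "
      f"{cbs_extrapolate(-1.000, -1.037, 3, 4):.4f}")
print("The QZ value carries weight Y³/(Y³−X³) = 64/37 ≈ 1.73; the")
print("extrapolation always overshoots the larger basis in its direction.")
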