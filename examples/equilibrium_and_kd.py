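"""Mass-action equilibria and the FCCS dissociation-constant equations.

Builds a two-colour binding mixture with a known dissociation constant,
then shows that the concentration equations used on fitted FCCS amplitudes
invert the equilibrium exactly.
"""

from cytofccs import (
    channel_concentration,
    complex_concentration,
    dissociation_constant,
    equilibrium_mixture,
)

# A ligand-receptor pair at 300 / 400 nM total with K_d = 600 nM.
mix = equilibrium_mixture(total_green=300.0, total_red=400.0, kd_true=600.0)
print(f"complex at equilibrium : {mix.complex:.1f} nM")
print(f"free ligand / receptor : {mix.free_green:.1f} / {mix.free_red:.1f} nM")

# K_d = (C_green - C_cc)(C_red - C_cc) / C_cc recovers the input exactly.
kd = dissociation_constant(mix.total_green, mix.total_red, mix.complex)
print(f"K_d from concentrations: {kd:.1f} nM (truth {mix.kd_true:.0f})")

# The same equations applied to fitted molecule numbers: N1, N2 from the
# two autocorrelations, N_cc = 1/G_cc(0) from the cross-correlation, in a
# 0.65-fl cross-correlation volume.
n1, n2, ncc, v_cc = 4.0, 5.0, 10.0, 0.65
c_cc = complex_concentration(n1, n2, ncc, v_cc)
print(f"\nN1={n1:.0f}, N2={n2:.0f}, N_cc={ncc:.0f} in V_cc={v_cc} fl")
print(f"  bound-complex concentration C_cc = {c_cc:.2f} nM")
print(f"  one molecule in 0.65 fl          = {channel_concentration(1.0, v_cc):.3f} nM")
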