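"""Rank compounds by electrophilicity from frontier-orbital energies.

Uses an illustrative panel shaped like the aniline bioactivation story:
the parent aromatic amine and its alert-free control have similar, modest
electrophilicity, while the two reactive-metabolite-like entries (lower
E_LUMO) come out far more electrophilic. Energies here are synthetic
illustrative values in hartree, not computed orbital energies.
"""

from adalert import FrontierOrbitalEnergies, rank_by_electrophilicity

panel = [
    FrontierOrbitalEnergies("aniline_like_parent", e_homo=-0.22, e_lumo=0.02),
    FrontierOrbitalEnergies("toluene_like_control", e_homo=-0.24, e_lumo=0.03),
    FrontierOrbitalEnergies("nitroso_metabolite_like", e_homo=-0.24, e_lumo=-0.08),
    FrontierOrbitalEnergies("quinone_imine_like", e_homo=-0.25, e_lumo=-0.10),
]

print(f"{'compound':<26} {'eta':>8} {'mu':>8} {'omega':>8} {'E_LUMO':>8}")
for compound, desc in rank_by_electrophilicity(panel):
    print(f"{compound.compound_id:<26} {desc.eta:>8.4f} {desc.mu:>8.4f} "
          f"{desc.omega:>8.4f} {compound.e_lumo:>8.3f}")
# omega = mu^2 / (2 eta) in hartree; the metabolite-like entries rank first
# because a deeper LUMO pulls mu more negative while narrowing the gap.
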