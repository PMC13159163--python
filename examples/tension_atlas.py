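"""Nucleation propensity across condensate and solid systems.

For each system of the interfacial-tension atlas (a representative,
synthetic-valued table of condensate and solid tensions), computes the
driving force Delta g_min at which nuclei form at the biologically relevant
rate J = 1e12 m^-3 s^-1. Condensates, with tensions of uJ/m^2 scale,
nucleate below the thermal energy RT ~ 2.5 kJ/mol; solids (crystals,
fibrils) need far larger driving forces -- the physical basis of the
distinct biological function space of condensates. Also shows the cell-
scale sensitivity of the nucleus count to a few-percent change in gamma.
"""

import phasekin as pk
from phasekin.io import read_tension_atlas

df = pk.atlas_delta_g_min(read_tension_atlas())
RT = pk.R_GAS * 300.0 / 1e3

print(f"RT at 300 K = {RT:.2f} kJ/mol")
print()
print("system                    class        gamma (uJ/m^2)    dg_min (kJ/mol)")
for _, r in df.sort_values(["klass", "delta_g_min_low_kJ_per_mol"]).iterrows():
    print(
        f"{r.system:<25} {r.klass:<11}"
        f" {r.gamma_low_J_per_m2 * 1e6:7.1f} - {r.gamma_high_J_per_m2 * 1e6:8.1f}"
        f"  {r.delta_g_min_low_kJ_per_mol:7.3f} - {r.delta_g_min_high_kJ_per_mol:7.3f}"
    )

cond = df[df.klass == "condensate"]
solid = df[df.klass == "solid"]
print()
print(f"all condensates below RT: {bool((cond.delta_g_min_high_kJ_per_mol < RT).all())}")
print(f"weakest solid needs {solid.delta_g_min_low_kJ_per_mol.min():.1f} kJ/mol "
      f"(> strongest condensate {cond.delta_g_min_high_kJ_per_mol.max():.2f})")

print()
print("cell-scale sensitivity (d = 60 um, D = 1e-10 m^2/s, gamma = 200 uJ/m^2):")
dg = -1.8e-21  # J per molecule (~ -1.1 kJ/mol, mid-range metastability)
counts = {}
for gamma in (190e-6, 200e-6, 210e-6):
    scn = pk.CellScenario(d_cell=60e-6, D=1e-10, gamma=gamma)
    counts[gamma] = pk.cell_nuclei(scn, dg, Mw=10.0)
base = counts[200e-6]
for gamma, n in counts.items():
    area = pk.surface_area_factor(n / base)
    print(f"  gamma = {gamma * 1e6:5.0f} uJ/m^2 -> N = {n:10.3e} nuclei "
          f"(total surface area x{area:.2f} vs gamma = 200)")
print("a 5% change in gamma moves the nucleus count by orders of magnitude,")
print("and the total condensate surface area with it (cube-root scaling)")
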