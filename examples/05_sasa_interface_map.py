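"""Interface mapping by SASA deletion differences, and reporter selection.

Uses a two-lobe toy structure with a designed contact layer: deleting one
lobe exposes surface on exactly the residues that touched it.  The same
structure then illustrates reporter selection — residues far from every
interface, whose shifts track only the conformational equilibrium.
"""

from confsel import deletion_diff, reporter_select
from confsel.synthetic import gen_toy_structure

structure, info = gen_toy_structure("two_lobe", gap=3.0)
diff = deletion_diff(structure, info["lobe_b"], threshold=5.0)

print(f"Deleted lobe B ({len(info['lobe_b'])} residues).")
print(f"Contact residues flagged (dSASA > 5 A^2): {diff.flagged}")
print(f"Designed contact layer:                   {info['contacts_a']}")
for res in diff.flagged[:3]:
    print(f"  residue {res}: dSASA = {diff.delta[res]:.1f} A^2")

reporters = reporter_select(structure, {"inter-lobe": info["contacts_a"]},
                            min_dist=8.0)
print(f"\n{len(reporters)} residues lie > 8 A from the interface and qualify")
print("as conformational reporters (their shifts are equilibrium-only).")

far, far_info = gen_toy_structure("two_lobe", gap=20.0)
far_diff = deletion_diff(far, far_info["lobe_b"])
print(f"\nWith a 20 A gap the same deletion flags {far_diff.flagged!r}:")
print("no contacts, no exposure change — the map is specific.")
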