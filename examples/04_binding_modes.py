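"""Key-residue identification and binding-mode analysis on a PDB fixture.

Builds a synthetic mini-Fab complex (chains H/L plus antigen chain A),
applies the 10 A center-of-mass rule for cross-CDR key residues, and
tabulates antigen contacts (heavy-atom pairs within 4 A) with hydrogen-bond
flags (donor-acceptor <= 3.5 A and donor-H-acceptor angle >= 120 degrees).
"""

import phmd
from phmd.structure import binding_modes, key_residue_pairs

fab = phmd.make_fab_fixture(phmd.FabLayout(include_antigen=True))
print(f"chains: {fab.chains}, atoms: {len(fab.df)}")

pairs = key_residue_pairs(fab, cutoff=10.0)
print(f"\nkey cross-CDR residue pairs (< 10 A COM distance): {len(pairs)}")
print(pairs.head(5).to_string(index=False))

print("\nbinding modes (contacting residues per region; HB = hydrogen bond):")
for record in binding_modes(fab, contact_cutoff=4.0):
    print(f"  {record.region:<22s} {record.format()}")
# Residues listed under a CDR region touch the antigen there; "Null" regions
# make no contact.  The designed 2.9 A donor-H...acceptor pair on H:103
# shows up with an (HB) flag.
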