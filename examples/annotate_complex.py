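"""Annotate a synthetic kinase-inhibitor complex end to end.

Builds a complex with two designed contacts (a hinge hydrogen bond and a
hydrophobic contact at the gatekeeper), writes it to standard files,
parses it back and runs the full annotation pipeline.
"""

import tempfile

import gemmi

from kinpocket import annotate_monomer, split_entry
from kinpocket.fixtures import (DesignedContact, FixtureSpec,
                                generate_complex, write_complex)

spec = FixtureSpec(
    source_id="demo", seed=11, rigid_jumble=True,
    contacts=(DesignedContact(47, "hbond_donor"),
              DesignedContact(45, "hydrophobic")),
    waters=("I4", "I5"), extras=("ion",))
fx = generate_complex(spec)

with tempfile.TemporaryDirectory() as d:
    paths = write_complex(fx, d)
    (monomer,) = split_entry(paths["pdb"])
    record = annotate_monomer(monomer,
                              dictionary=gemmi.cif.read(str(paths["dictionary"])))

print(f"entry            : {record.entry_id}")
print(f"pocket sequence  : {record.pocket_sequence}")
print(f"DFG / aC classes : {record.dfg} / {record.alpha_c}")
print(f"anchor RMSD      : {record.rmsd_anchor:.3f} A   "
      f"pocket RMSD: {record.rmsd_pocket:.3f} A")
print(f"quality score    : {record.quality_score:.1f} / 10")
print(f"IFP set bits     : {record.ifp.on_bits()}")
print(f"water clusters   : {record.water_labels}")
print(f"subpockets hit   : {sorted(k for k, v in record.subpockets.items() if v)}")

# The two designed contacts appear as one hydrogen-bond bit in the hinge
# block (slot 47) and a hydrophobic bit at the gatekeeper (slot 45); the
# zero RMSD values confirm the arbitrary rigid pose was undone by the
# anchor superposition, giving the maximal quality score of 10.
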