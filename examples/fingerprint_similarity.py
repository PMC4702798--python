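"""Compare interaction fingerprints of two complexes.

Two ligands sharing the hinge hydrogen bond but differing at the
gatekeeper give a Tanimoto similarity below 1; a pattern query for the
hinge bond matches both.
"""

from kinpocket import InteractionPattern, compute_ifp, ifp_similarity, match_pattern
from kinpocket.fixtures import DesignedContact, FixtureSpec, generate_complex
from kinpocket.scaffold import pocket_of_domain

a = generate_complex(FixtureSpec(
    source_id="a", contacts=(DesignedContact(47, "hbond_donor"),)))
b = generate_complex(FixtureSpec(
    source_id="b", contacts=(DesignedContact(47, "hbond_donor"),
                             DesignedContact(45, "hydrophobic"))))

fp_a = compute_ifp(pocket_of_domain(a.monomer), a.ligand)
fp_b = compute_ifp(pocket_of_domain(b.monomer), b.ligand)

print(f"fingerprint length : {len(fp_a)} bits (85 residues x 7 types)")
print(f"bits A             : {fp_a.on_bits()}")
print(f"bits B             : {fp_b.on_bits()}")
print(f"Tanimoto similarity: {ifp_similarity(fp_a, fp_b):.3f}")

hinge_bond = InteractionPattern(((47, "hbond_donor", "present"),))
print(f"hinge H-bond in A  : {match_pattern(fp_a, hinge_bond)}")
print(f"hinge H-bond in B  : {match_pattern(fp_b, hinge_bond)}")

# A's single bit is a subset of B's three, so the similarity equals
# |A & B| / |A | B| = 1/3; both fingerprints satisfy the hinge-bond
# pattern constraint.
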